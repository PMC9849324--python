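"""Top-level pipeline: simulate → dvc → traction → quantify → stats.

A run is described by a plain-dict config (usually loaded from YAML).
Every stage writes its artifacts plus a manifest recording the inputs,
parameters, seed and package version, so any run is reconstructible from
the manifest alone and a rerun with the same config reproduces all
deterministic outputs bit-exactly (manifests differ only in timestamp).
"""

from __future__ import annotations

import datetime
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import __version__
from .core import GelModel
from .dvc import DvcParams, run_dvc
from .fields import closed_form_traction
from .io import (
    read_channels,
    read_field_csv,
    read_volume,
    write_channels,
    write_field_csv,
    write_json,
    write_traction_csv,
    write_volume,
)
from .mechanics import average_traction, traction_from_displacement
from .quant import quantify_cell
from .stats import GroupSample, route_multi_group_test, route_two_group_test
from .synthetic import CellSceneConfig, SceneConfig, generate_cell_image, make_scene_pair

log = logging.getLogger("stemmech")

STAGES = ("simulate", "dvc", "traction", "quantify", "stats")


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Execute the requested stages in order and return a result bundle.

    ``config`` keys: ``stages`` (ordered subset of simulate/dvc/traction/
    quantify/stats), ``seed``, plus per-stage parameter blocks. Stage
    dependencies are validated before any work starts: ``dvc`` needs the
    simulated (or supplied) volume pair, ``traction`` needs a displacement
    field, ``stats`` needs metrics.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", STAGES))
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    _check_dependencies(stages, config)

    seed = int(config.get("seed", 0))
    bundle: dict[str, Any] = {"out_dir": str(out)}
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": seed,
        "stages": stages,
        "config": _plain(config),
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "artifacts": {},
    }

    if "simulate" in stages:
        _stage_simulate(config, seed, out, bundle, manifest)
    if "dvc" in stages:
        _stage_dvc(config, out, bundle, manifest)
    if "traction" in stages:
        _stage_traction(config, out, bundle, manifest)
    if "quantify" in stages:
        _stage_quantify(config, seed, out, bundle, manifest)
    if "stats" in stages:
        _stage_stats(config, out, bundle, manifest)

    write_json(out / "manifest.json", manifest)
    bundle["manifest"] = manifest
    return bundle


def _check_dependencies(stages: list[str], config: Mapping[str, Any]) -> None:
    have_volumes = "simulate" in stages or "volumes" in config
    if "dvc" in stages and not have_volumes:
        raise ValueError("stage 'dvc' needs 'simulate' or a 'volumes' config block")
    if "traction" in stages and "dvc" not in stages and "field_csv" not in config:
        raise ValueError("stage 'traction' needs 'dvc' or a 'field_csv' path")
    if "stats" in stages and "quantify" not in stages and "metrics" not in config:
        raise ValueError("stage 'stats' needs 'quantify' or a 'metrics' config block")


def _stage_simulate(config, seed, out, bundle, manifest) -> None:
    sim = dict(config.get("simulate", {}))
    spec = sim.pop("displacement_spec", {"name": "shear", "gamma": 0.01})
    gel = _gel_from_config(config)
    scene = SceneConfig(rng_seed=seed, displacement_spec=spec, gel=gel, **sim)
    ref, deformed, truth = make_scene_pair(scene, spec)
    write_volume(out / "ref.tif", ref)
    write_volume(out / "deformed.tif", deformed)
    bundle.update(ref=ref, deformed=deformed, truth=truth, displacement_spec=spec)
    manifest["artifacts"]["simulate"] = {"ref": "ref.tif", "deformed": "deformed.tif"}
    log.info("simulate: %d beads, spec %s", len(truth.bead_positions_um), spec)


def _stage_dvc(config, out, bundle, manifest) -> None:
    params = DvcParams(**config.get("dvc", {}))
    if "ref" in bundle:
        ref, deformed = bundle["ref"], bundle["deformed"]
    else:
        vols = config["volumes"]
        ref = read_volume(vols["ref"], vols.get("voxel_size_um"))
        deformed = read_volume(vols["deformed"], vols.get("voxel_size_um"))
    field = run_dvc(ref, deformed, params)
    write_field_csv(out / "field.csv", field)
    bundle["field"] = field
    n_bad = int((~field.valid).sum())
    if n_bad:
        log.warning("dvc: %d nodes failed correlation", n_bad)
    manifest["artifacts"]["dvc"] = {"field": "field.csv", "invalid_nodes": n_bad}


def _stage_traction(config, out, bundle, manifest) -> None:
    gel = _gel_from_config(config)
    field = bundle.get("field")
    if field is None:
        field = read_field_csv(config["field_csv"])
    result = traction_from_displacement(field, gel)
    avg_txy, avg_tzz = average_traction(result)
    write_traction_csv(out / "traction.csv", result)
    summary = {"avg_Txy_Pa": avg_txy, "avg_Tzz_Pa": avg_tzz, "E_kPa": gel.young_modulus_kpa}
    spec = bundle.get("displacement_spec")
    if spec is not None:
        oracle = closed_form_traction(spec, gel, result.y_um, result.x_um)
        summary["closed_form_avg_Txy_Pa"] = float(oracle.txy.mean())
        summary["closed_form_avg_Tzz_Pa"] = float(oracle.tzz.mean())
    write_json(out / "traction_summary.json", summary)
    bundle.update(traction=result, traction_summary=summary)
    manifest["artifacts"]["traction"] = {
        "traction": "traction.csv",
        "summary": "traction_summary.json",
    }
    log.info("traction: avg |Txy| = %.2f Pa, avg |Tzz| = %.2f Pa", avg_txy, avg_tzz)


def _stage_quantify(config, seed, out, bundle, manifest) -> None:
    q = dict(config.get("quantify", {}))
    size_range = tuple(q.pop("size_range_um2", (0.1, 15.0)))
    if "image" in q:
        channels, pixel = read_channels(q["image"])
    else:
        scene = CellSceneConfig(rng_seed=seed, **q)
        channels, truth = generate_cell_image(scene)
        pixel = scene.pixel_size_um
        write_channels(out / "cell.tif", channels, pixel)
        bundle["cell_truth"] = truth
    metrics = quantify_cell(channels, pixel, size_range)
    write_json(out / "metrics.json", vars(metrics).copy())
    bundle["metrics"] = metrics
    manifest["artifacts"]["quantify"] = {"metrics": "metrics.json"}


def _stage_stats(config, out, bundle, manifest) -> None:
    block = config.get("stats", {})
    groups = [
        GroupSample(label=g["label"], values=np.asarray(g["values"], dtype=float))
        for g in block.get("groups", [])
    ]
    if len(groups) < 2:
        raise ValueError("stats stage needs at least two groups of values")
    if len(groups) == 2:
        res = route_two_group_test(groups[0], groups[1])
    else:
        res = route_multi_group_test(groups)
    payload = {
        "test": res.test_name,
        "statistic": res.statistic,
        "p": res.p_value,
        "stars": res.stars,
        "gate": res.gate_decision,
    }
    write_json(out / "stats.json", payload)
    bundle["stats"] = payload
    manifest["artifacts"]["stats"] = {"stats": "stats.json"}


def _gel_from_config(config: Mapping[str, Any]) -> GelModel:
    g = config.get("gel", {})
    return GelModel(
        young_modulus_kpa=float(g.get("young_modulus_kpa", 14.0)),
        poisson_ratio=float(g.get("poisson_ratio", 0.5)),
    )


def _plain(obj):
    if isinstance(obj, Mapping):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
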