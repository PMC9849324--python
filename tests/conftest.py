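"""Shared fixtures: compact scenes sized for fast unit tests.

The default generator geometry (64 × 128 × 128 voxels) is reserved for the
acceptance suite; unit and property tests run on a smaller gel block that
still fits several correlation subsets per axis.
"""

from __future__ import annotations

import numpy as np
import pytest

from stemmech.core import GelModel
from stemmech.dvc import DvcParams
from stemmech.synthetic import CellSceneConfig, SceneConfig, generate_bead_volume, make_scene_pair


@pytest.fixture(scope="session")
def gel14() -> GelModel:
    return GelModel(young_modulus_kpa=14.0, poisson_ratio=0.5)


@pytest.fixture(scope="session")
def small_config() -> SceneConfig:
    return SceneConfig(rng_seed=11, volume_shape=(48, 96, 96))


@pytest.fixture(scope="session")
def small_volume(small_config):
    vol, truth = generate_bead_volume(small_config)
    return vol


@pytest.fixture(scope="session")
def small_params() -> DvcParams:
    return DvcParams()


@pytest.fixture(scope="session")
def shear_pair(small_config):
    """Reference/deformed pair for a 1% simple shear on the small gel."""
    return make_scene_pair(small_config, {"name": "shear", "gamma": 0.01})


@pytest.fixture(scope="session")
def cell_scene():
    cfg = CellSceneConfig(rng_seed=7, n_fa_puncta=12, yap_nc_ratio_true=3.0)
    channels, truth = __import__("stemmech.synthetic", fromlist=["generate_cell_image"]).generate_cell_image(cfg)
    return cfg, channels, truth


def analytic_field(spec, gel=None, shape=(9, 17, 17), extent=25.6):
    """Displacement spec sampled on a regular analytic node grid."""
    from stemmech.core import DisplacementField
    from stemmech.fields import evaluate_displacement

    z = np.linspace(0.0, extent, shape[0])
    y = np.linspace(0.0, extent, shape[1])
    x = np.linspace(0.0, extent, shape[2])
    zz, yy, xx = np.meshgrid(z, y, x, indexing="ij")
    ux, uy, uz = evaluate_displacement(spec, zz, yy, xx)
    return DisplacementField(z, y, x, ux, uy, uz)
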