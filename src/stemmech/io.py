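"""Readers and writers for the pipeline's on-disk formats.

Volumes and multi-channel images travel as multi-page TIFF (ZYX or CYX,
16-bit on write) with a JSON sidecar carrying the voxel/pixel size;
displacement fields and tractions as CSV with units in the column names;
summaries and run manifests as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import DisplacementField, TractionResult, VoxelVolume

__all__ = [
    "read_volume",
    "write_volume",
    "write_channels",
    "read_channels",
    "write_field_csv",
    "read_field_csv",
    "write_traction_csv",
    "write_json",
    "read_json",
]

FIELD_COLUMNS = ["x_um", "y_um", "z_um", "ux_um", "uy_um", "uz_um", "score", "valid"]
TRACTION_COLUMNS = ["x_um", "y_um", "Tx_Pa", "Ty_Pa", "Tz_Pa", "Txy_Pa", "Tzz_Pa"]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_volume(path: str | Path, volume: VoxelVolume) -> None:
    """Write a volume as multi-page TIFF (ZYX) plus a voxel-size sidecar.

    Intensities are scaled to the full 16-bit range on write; the scale is
    recorded in the sidecar so a read round-trips to the same values.
    """
    path = Path(path)
    data = volume.data
    scale = _uint16_scale(data)
    tifffile.imwrite(path, np.clip(np.round(data * scale), 0, 65535).astype(np.uint16),
                     photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps({"voxel_size_um": list(volume.voxel_size), "intensity_scale": scale})
    )


def _uint16_scale(data: np.ndarray) -> float:
    """Scale factor into the uint16 range; 1.0 if the data already fits exactly."""
    if data.size == 0:
        return 1.0
    lo, hi = float(data.min()), float(data.max())
    if lo >= 0 and hi <= 65535 and np.array_equal(data, np.round(data)):
        return 1.0
    return (65535.0 / hi) if hi > 0 else 1.0


def read_volume(
    path: str | Path, voxel_size_um: tuple[float, float, float] | None = None
) -> VoxelVolume:
    """Read a multi-page TIFF as a volume.

    The voxel size comes from the JSON sidecar written by
    :func:`write_volume`, or must be passed explicitly; a missing size is a
    hard error, never a silent default.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        shapes = {p.shape for p in tif.pages}
        if len(shapes) > 1:
            raise ValueError(f"{path}: TIFF pages have ragged shapes {sorted(shapes)}")
        data = tif.asarray().astype(float)
    if data.ndim == 2:
        data = data[None]
    scale = 1.0
    sc = _sidecar(path)
    if voxel_size_um is None:
        if not sc.exists():
            raise ValueError(
                f"{path}: no voxel-size sidecar found and no voxel size given; "
                "pass voxel_size_um explicitly"
            )
        meta = json.loads(sc.read_text())
        voxel_size_um = tuple(meta["voxel_size_um"])
        scale = float(meta.get("intensity_scale", 1.0))
    elif sc.exists():
        scale = float(json.loads(sc.read_text()).get("intensity_scale", 1.0))
    return VoxelVolume(data=data / scale if scale != 1.0 else data, voxel_size=voxel_size_um)


def write_channels(
    path: str | Path, channels: dict[str, np.ndarray], pixel_size_um: float
) -> None:
    """Write a CYX multi-channel 2D image stack with channel names in a sidecar."""
    path = Path(path)
    names = list(channels)
    stack = np.stack([channels[n] for n in names])
    scale = _uint16_scale(stack)
    tifffile.imwrite(path, np.clip(np.round(stack * scale), 0, 65535).astype(np.uint16),
                     photometric="minisblack")
    _sidecar(path).write_text(
        json.dumps(
            {"channels": names, "pixel_size_um": pixel_size_um, "intensity_scale": scale}
        )
    )


def read_channels(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    """Read a CYX stack written by :func:`write_channels`."""
    path = Path(path)
    meta = json.loads(_sidecar(path).read_text())
    stack = tifffile.imread(path).astype(float) / float(meta.get("intensity_scale", 1.0))
    if stack.ndim == 2:
        stack = stack[None]
    channels = {name: stack[i] for i, name in enumerate(meta["channels"])}
    return channels, float(meta["pixel_size_um"])


def write_field_csv(path: str | Path, field: DisplacementField) -> None:
    zz, yy, xx = np.meshgrid(field.z_um, field.y_um, field.x_um, indexing="ij")
    df = pd.DataFrame(
        {
            "x_um": xx.ravel(),
            "y_um": yy.ravel(),
            "z_um": zz.ravel(),
            "ux_um": field.ux.ravel(),
            "uy_um": field.uy.ravel(),
            "uz_um": field.uz.ravel(),
            "score": field.score.ravel(),
            "valid": field.valid.ravel().astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_field_csv(path: str | Path) -> DisplacementField:
    df = pd.read_csv(path)
    missing = set(FIELD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    z = np.unique(df["z_um"])
    y = np.unique(df["y_um"])
    x = np.unique(df["x_um"])
    shape = (len(z), len(y), len(x))
    if len(df) != np.prod(shape):
        raise ValueError(f"{path}: rows do not form a full regular grid")
    df = df.sort_values(["z_um", "y_um", "x_um"])
    return DisplacementField(
        z_um=z,
        y_um=y,
        x_um=x,
        ux=df["ux_um"].to_numpy().reshape(shape),
        uy=df["uy_um"].to_numpy().reshape(shape),
        uz=df["uz_um"].to_numpy().reshape(shape),
        score=df["score"].to_numpy().reshape(shape),
        valid=df["valid"].to_numpy().astype(bool).reshape(shape),
    )


def write_traction_csv(path: str | Path, result: TractionResult) -> None:
    yy, xx = np.meshgrid(result.y_um, result.x_um, indexing="ij")
    pd.DataFrame(
        {
            "x_um": xx.ravel(),
            "y_um": yy.ravel(),
            "Tx_Pa": result.tx.ravel(),
            "Ty_Pa": result.ty.ravel(),
            "Tz_Pa": result.tz.ravel(),
            "Txy_Pa": result.txy.ravel(),
            "Tzz_Pa": result.tzz.ravel(),
        }
    ).to_csv(path, index=False)


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
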