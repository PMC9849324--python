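"""Shared data containers for the traction-stress pipeline.

Conventions used throughout the package:

* Grids are indexed ``[z, y, x]`` (axis 0 is the optical axis, increasing
  toward the gel surface).
* Vector and tensor *components* are indexed ``0 = x, 1 = y, 2 = z``, so a
  stress tensor field has shape ``(nz, ny, nx, 3, 3)``.
* Physical coordinates are in micrometres measured from the volume origin
  at voxel centres; stresses are in pascal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "VoxelVolume",
    "GelModel",
    "DisplacementField",
    "TensorField",
    "TractionResult",
]


@dataclass
class VoxelVolume:
    """A 3D scalar intensity grid with anisotropic voxel size.

    Parameters
    ----------
    data
        Intensity array of shape ``(nz, ny, nx)``.
    voxel_size
        ``(dz, dy, dx)`` in micrometres.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite intensities")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def axis_coords_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates (z_um, y_um, x_um) of voxel centres along each axis."""
        return tuple(
            np.arange(n) * d for n, d in zip(self.data.shape, self.voxel_size)
        )


@dataclass
class GelModel:
    """Linear-elastic description of the polyacrylamide substrate.

    The constitutive relation used everywhere downstream is
    ``sigma = E * eps / (1 + nu)`` with the gel treated as incompressible
    (``nu = 0.5``) by default, and tractions follow from ``T = sigma . n``.
    """

    young_modulus_kpa: float
    poisson_ratio: float = 0.5
    surface_normal: tuple[float, float, float] = (0.0, 0.0, 1.0)  # (nx, ny, nz)

    def __post_init__(self) -> None:
        if self.young_modulus_kpa <= 0:
            raise ValueError("Young's modulus must be positive")
        if self.poisson_ratio == -1.0:
            raise ValueError("invalid gel model: poisson_ratio = -1 (singular constitutive relation)")
        n = np.asarray(self.surface_normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("surface normal must be non-zero")
        if not np.isclose(norm, 1.0):
            import warnings

            warnings.warn("surface normal was not unit length; normalizing", stacklevel=2)
            n = n / norm
        self.surface_normal = tuple(float(v) for v in n)

    @property
    def young_modulus_pa(self) -> float:
        return self.young_modulus_kpa * 1000.0


@dataclass
class DisplacementField:
    """Displacement vectors on a regular node grid.

    ``ux/uy/uz`` are in micrometres on the ``(nz, ny, nx)`` node grid whose
    physical node positions are given by the 1D coordinate arrays.
    ``score`` is the normalized cross-correlation value per node and
    ``valid`` flags nodes that passed the acceptance threshold.
    """

    z_um: np.ndarray
    y_um: np.ndarray
    x_um: np.ndarray
    ux: np.ndarray
    uy: np.ndarray
    uz: np.ndarray
    score: np.ndarray = field(default=None)  # type: ignore[assignment]
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = (len(self.z_um), len(self.y_um), len(self.x_um))
        for name in ("ux", "uy", "uz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)
        if self.score is None:
            self.score = np.ones(shape)
        if self.valid is None:
            self.valid = np.ones(shape, dtype=bool)
        self.score = np.asarray(self.score, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        for comp in (self.ux, self.uy, self.uz):
            if not np.all(np.isfinite(comp[self.valid])):
                raise ValueError("non-finite displacement on valid nodes")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.z_um), len(self.y_um), len(self.x_um))

    def node_spacing_um(self) -> tuple[float, float, float]:
        def step(c: np.ndarray) -> float:
            return float(c[1] - c[0]) if len(c) > 1 else 1.0

        return (step(self.z_um), step(self.y_um), step(self.x_um))


@dataclass
class TensorField:
    """Symmetric rank-2 tensor per node: strain (dimensionless) or stress (Pa)."""

    z_um: np.ndarray
    y_um: np.ndarray
    x_um: np.ndarray
    tensor: np.ndarray  # (nz, ny, nx, 3, 3), components ordered x, y, z
    kind: Literal["strain", "stress"]
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=float)
        expected = (len(self.z_um), len(self.y_um), len(self.x_um), 3, 3)
        if self.tensor.shape != expected:
            raise ValueError(f"tensor shape {self.tensor.shape}, expected {expected}")
        if self.valid is None:
            self.valid = np.ones(self.tensor.shape[:3], dtype=bool)
        sym_err = np.abs(self.tensor - np.swapaxes(self.tensor, -1, -2))
        if np.nanmax(sym_err[self.valid]) > 1e-8 * (1 + np.nanmax(np.abs(self.tensor))):
            raise ValueError(f"{self.kind} tensor is not symmetric")


@dataclass
class TractionResult:
    """Surface traction vectors and their in-plane / out-of-plane magnitudes.

    ``Txy = sqrt(Tx^2 + Ty^2)`` is the in-plane (shear) traction magnitude
    and ``Tzz = |Tz|`` the out-of-plane (normal) magnitude, both in Pa on
    the surface node grid.
    """

    y_um: np.ndarray
    x_um: np.ndarray
    tx: np.ndarray
    ty: np.ndarray
    tz: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = (len(self.y_um), len(self.x_um))
        for name in ("tx", "ty", "tz"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
            setattr(self, name, arr)
        if self.valid is None:
            self.valid = np.ones(shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def txy(self) -> np.ndarray:
        """In-plane traction magnitude map |Txy| (Pa)."""
        return np.hypot(self.tx, self.ty)

    @property
    def tzz(self) -> np.ndarray:
        """Out-of-plane traction magnitude map |Tzz| (Pa)."""
        return np.abs(self.tz)
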