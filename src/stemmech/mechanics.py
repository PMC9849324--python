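"""Strain, stress and surface traction from a displacement field.

The chain implemented here is deliberately local and linear:

1. small-strain tensor ``eps = (grad u + grad u^T) / 2`` by central
   differences on the node grid (second-order one-sided at the edges);
2. the gel's constitutive relation ``sigma = E * eps / (1 + nu)`` applied
   componentwise, with the gel treated as incompressible (``nu = 0.5``);
3. the Cauchy relation ``T = sigma . n`` evaluated on the top (highest-z)
   node layer with outward normal ``n = (0, 0, 1)``, decomposed into the
   in-plane magnitude ``|Txy| = sqrt(Tx^2 + Ty^2)`` and the out-of-plane
   magnitude ``|Tzz| = |Tz|``.

Note the constitutive relation is the shear-only form ``2 mu eps`` at
``nu = 0.5``; it carries no hydrostatic pressure term. That is a property
of the reconstruction protocol this package reproduces, and the closed-form
oracle in :mod:`stemmech.fields` uses the identical rule, so the two are
directly comparable.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import DisplacementField, GelModel, TensorField, TractionResult

__all__ = [
    "compute_strain",
    "compute_stress",
    "compute_traction",
    "average_traction",
    "traction_from_displacement",
]


def compute_strain(field: DisplacementField) -> TensorField:
    """Small-strain tensor per node, symmetric by construction.

    Gradients are taken on the physical node grid (μm), so strain is
    dimensionless. Nodes flagged invalid in the input are first filled with
    a local median of their valid neighbours so the finite-difference
    stencil stays usable; nodes that remain unfillable propagate as
    invalid.
    """
    if any(n < 3 for n in field.shape):
        raise ValueError("need at least 3 nodes per axis for strain gradients")
    comps = []
    valid = field.valid.copy()
    for u in (field.ux, field.uy, field.uz):
        filled, ok = _fill_invalid(u, field.valid)
        valid &= ok
        comps.append(filled)
    ux, uy, uz = comps

    # np.gradient axes are (z, y, x); component indices are (x, y, z)
    grads = {}
    for ci, u in ((0, ux), (1, uy), (2, uz)):
        dz, dy, dx = np.gradient(u, field.z_um, field.y_um, field.x_um)
        grads[ci] = (dx, dy, dz)  # d u_ci / d (x, y, z)

    nz, ny_, nx_ = field.shape
    eps = np.zeros((nz, ny_, nx_, 3, 3))
    for i in range(3):
        for j in range(3):
            eps[..., i, j] = 0.5 * (grads[i][j] + grads[j][i])
    return TensorField(
        z_um=field.z_um, y_um=field.y_um, x_um=field.x_um,
        tensor=eps, kind="strain", valid=valid,
    )


def _fill_invalid(u: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fill invalid nodes with the median of valid neighbours (3³ window)."""
    if valid.all():
        return u, valid
    masked = np.where(valid, u, np.nan)
    med = ndimage.generic_filter(masked, np.nanmedian, size=3, mode="nearest")
    filled = np.where(valid, u, med)
    ok = valid | np.isfinite(med)
    return np.where(np.isfinite(filled), filled, 0.0), ok


def compute_stress(strain: TensorField, gel: GelModel) -> TensorField:
    """Componentwise constitutive map ``sigma = E * eps / (1 + nu)`` in Pa."""
    if strain.kind != "strain":
        raise ValueError(f"expected a strain field, got {strain.kind!r}")
    sigma = gel.young_modulus_pa * strain.tensor / (1.0 + gel.poisson_ratio)
    return TensorField(
        z_um=strain.z_um, y_um=strain.y_um, x_um=strain.x_um,
        tensor=sigma, kind="stress", valid=strain.valid,
    )


def compute_traction(stress: TensorField, gel: GelModel) -> TractionResult:
    """Cauchy traction ``T = sigma . n`` on the top surface node layer."""
    if stress.kind != "stress":
        raise ValueError(f"expected a stress field, got {stress.kind!r}")
    n = np.asarray(gel.surface_normal)
    # highest-z layer containing any valid node
    layer_valid = stress.valid.any(axis=(1, 2))
    if not layer_valid.any():
        raise ValueError("no valid nodes in the stress field")
    iz = int(np.max(np.nonzero(layer_valid)[0]))
    sigma_surf = stress.tensor[iz]  # (ny, nx, 3, 3)
    t = sigma_surf @ n  # (ny, nx, 3)
    return TractionResult(
        y_um=stress.y_um,
        x_um=stress.x_um,
        tx=t[..., 0],
        ty=t[..., 1],
        tz=t[..., 2],
        valid=stress.valid[iz],
    )


def average_traction(
    result: TractionResult, cell_mask: np.ndarray | None = None
) -> tuple[float, float]:
    """Per-cell mean in-plane and out-of-plane traction magnitudes (Pa).

    ``cell_mask`` is a boolean array on the surface node grid (the caller
    resamples a pixel-resolution cell outline onto the node grid first); if
    omitted the average runs over all valid surface nodes.
    """
    sel = result.valid.copy()
    if cell_mask is not None:
        cell_mask = np.asarray(cell_mask, dtype=bool)
        if cell_mask.shape != sel.shape:
            raise ValueError(
                f"mask shape {cell_mask.shape} does not match surface grid {sel.shape}"
            )
        sel &= cell_mask
    if sel.sum() < 4:
        raise ValueError("cell mask overlaps fewer than 4 valid surface nodes")
    return float(result.txy[sel].mean()), float(result.tzz[sel].mean())


def traction_from_displacement(
    field: DisplacementField, gel: GelModel
) -> TractionResult:
    """Convenience chain: displacement → strain → stress → surface traction."""
    return compute_traction(compute_stress(compute_strain(field), gel), gel)
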