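"""Analytic displacement fields and their exact surface tractions.

A small library of named displacement specs serves double duty: it drives
the synthetic bead-volume deformation, and it supplies the closed-form
traction that the numerical strain → stress → traction chain must match.
Each spec is a plain mapping ``{"name": <str>, ...params}``.

Available specs (coordinates in μm, displacements in μm):

``constant``
    Rigid translation ``u = shift_um``; zero strain, zero traction.
``shear``
    Simple shear ``u = (gamma * z, 0, 0)``; surface traction
    ``Tx = E * gamma / (2 * (1 + nu))``.
``uniaxial``
    Axial stretch ``u = (0, 0, beta * z)``; surface traction
    ``Tz = E * beta / (1 + nu)``.
``rotation``
    Small rigid rotation about the z axis through ``center_um``;
    antisymmetric gradient, zero traction.
``gaussian_bump``
    Localized in-plane shear: ``ux = amp_um * g(x, y) * z / depth_um`` with
    ``g`` a unit-height Gaussian of width ``sigma_um`` at ``center_um``;
    surface traction ``Tx = E * amp_um * g / (2 * depth_um * (1 + nu))``.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .core import GelModel, TractionResult

__all__ = [
    "KNOWN_SPECS",
    "evaluate_displacement",
    "closed_form_traction",
]

KNOWN_SPECS = ("constant", "shear", "uniaxial", "rotation", "gaussian_bump")


def _check_spec(spec: Mapping) -> str:
    name = spec.get("name")
    if name not in KNOWN_SPECS:
        raise ValueError(f"unknown displacement spec {name!r}; known: {KNOWN_SPECS}")
    return name


def _bump(spec: Mapping, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    x0, y0 = spec.get("center_um", (0.0, 0.0))
    s = float(spec["sigma_um"])
    return np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2.0 * s * s))


def evaluate_displacement(
    spec: Mapping, z_um: np.ndarray, y_um: np.ndarray, x_um: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Evaluate ``(ux, uy, uz)`` in μm at broadcastable coordinate arrays."""
    name = _check_spec(spec)
    z, y, x = np.broadcast_arrays(
        np.asarray(z_um, dtype=float),
        np.asarray(y_um, dtype=float),
        np.asarray(x_um, dtype=float),
    )
    zero = np.zeros_like(x)
    if name == "constant":
        sx, sy, sz = spec["shift_um"]
        return zero + sx, zero + sy, zero + sz
    if name == "shear":
        gamma = float(spec["gamma"])
        return gamma * z, zero, zero
    if name == "uniaxial":
        beta = float(spec["beta"])
        return zero, zero, beta * z
    if name == "rotation":
        omega = float(spec["omega_rad"])
        x0, y0 = spec.get("center_um", (0.0, 0.0))
        return -omega * (y - y0), omega * (x - x0), zero
    # gaussian_bump
    amp = float(spec["amp_um"])
    depth = float(spec["depth_um"])
    return amp * _bump(spec, x, y) * z / depth, zero, zero


def closed_form_traction(
    spec: Mapping,
    gel: GelModel,
    y_um: np.ndarray,
    x_um: np.ndarray,
) -> TractionResult:
    """Exact surface traction of an analytic spec under ``sigma = E eps/(1+nu)``.

    The traction is evaluated on the ``(y_um, x_um)`` surface grid with the
    gel normal ``n = (0, 0, 1)``; it is independent of the surface height for
    every spec in the library (their strain tensors do not vary with z).
    """
    name = _check_spec(spec)
    y_um = np.asarray(y_um, dtype=float)
    x_um = np.asarray(x_um, dtype=float)
    yy, xx = np.meshgrid(y_um, x_um, indexing="ij")
    modulus = gel.young_modulus_pa / (1.0 + gel.poisson_ratio)
    tx = np.zeros_like(xx)
    ty = np.zeros_like(xx)
    tz = np.zeros_like(xx)
    if name == "shear":
        # eps_xz = gamma / 2  ->  sigma_xz = E gamma / (2 (1 + nu))
        tx += modulus * float(spec["gamma"]) / 2.0
    elif name == "uniaxial":
        # eps_zz = beta  ->  sigma_zz = E beta / (1 + nu)
        tz += modulus * float(spec["beta"])
    elif name == "gaussian_bump":
        # eps_xz = amp g(x,y) / (2 depth)
        amp = float(spec["amp_um"])
        depth = float(spec["depth_um"])
        tx += modulus * amp * _bump(spec, xx, yy) / (2.0 * depth)
    # constant and rotation: rigid motions, zero strain, zero traction
    return TractionResult(y_um=y_um, x_um=x_um, tx=tx, ty=ty, tz=tz)
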