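"""Subset-based digital volume correlation.

Recovers the 3D displacement field between a reference (relaxed, after cell
release) and a deformed (stressed, cell attached) bead volume. Cubic
subsets are extracted on a regular node grid and matched in two passes:
a coarse integer shift from zero-mean FFT circular cross-correlation of
co-located windows, then a normalized cross-correlation of the reference
subset against a slightly larger search region of the deformed volume
centred at the shifted location (template matching), whose peak is refined
to sub-voxel precision with a separable three-point quadratic or Gaussian
fit. The second pass matters: correlating two subsets cropped at the same
window truncates boundary beads identically in both, which pulls the
correlation peak toward zero lag; matching the template against uncropped
deformed data removes that bias. Nodes whose correlation score falls below
an acceptance threshold are flagged invalid, and isolated outliers among
the valid nodes are replaced by a local component-wise median.

The sign convention: ``u`` maps the reference state to the deformed state,
so features in the deformed volume sit at ``x + u`` relative to the
reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from scipy.fft import fftn, ifftn

from .core import DisplacementField, VoxelVolume

__all__ = ["DvcParams", "correlate_subset", "subpixel_refine", "run_dvc"]


@dataclass
class DvcParams:
    """Correlation parameters.

    ``subset_size`` is the cubic window edge in voxels (odd, >= 9);
    ``grid_spacing`` the node pitch in voxels; ``min_correlation`` the
    score below which a node is discarded; ``outlier_median_window`` the
    edge of the median neighbourhood used for outlier replacement and
    ``outlier_tol_voxels`` the residual (in voxels) beyond which a node is
    replaced by that local median.
    """

    subset_size: int = 25
    grid_spacing: int = 8
    subpixel_method: str = "gaussian"
    min_correlation: float = 0.5
    outlier_median_window: int = 3
    outlier_tol_voxels: float = 1.0
    search_margin: int = 3  # half-width of the residual template-matching search, voxels
    smooth_window: int = 13  # local-linear smoothing window over nodes; 0 disables
    subtract_rigid: bool = False  # remove the global median displacement (stage drift)

    def __post_init__(self) -> None:
        if self.subset_size < 9 or self.subset_size % 2 == 0:
            raise ValueError("subset_size must be odd and >= 9")
        if not 0.0 <= self.min_correlation <= 1.0:
            raise ValueError("min_correlation must lie in [0, 1]")
        if self.subpixel_method not in ("quadratic", "gaussian"):
            raise ValueError("subpixel_method must be 'quadratic' or 'gaussian'")


def correlate_subset(
    ref_window: np.ndarray, def_window: np.ndarray
) -> tuple[tuple[int, int, int], float, np.ndarray]:
    """Normalized circular cross-correlation of two congruent windows.

    Returns ``(shift, score, corr)`` where ``shift`` is the integer
    displacement (in voxels, per axis, wrapped to ``[-n/2, n/2)``) that best
    maps the reference onto the deformed window, ``score`` the normalized
    correlation value at the peak (in ``[-1, 1]``) and ``corr`` the full
    correlation volume (fftshifted so zero shift is at the centre), kept for
    sub-voxel refinement.

    A zero-variance window cannot be matched; such subsets return
    ``score = nan`` and are flagged invalid by the caller rather than
    raising.
    """
    a = np.asarray(ref_window, dtype=float)
    b = np.asarray(def_window, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"window shapes differ: {a.shape} vs {b.shape}")
    a0 = a - a.mean()
    b0 = b - b.mean()
    denom = np.sqrt((a0**2).sum() * (b0**2).sum())
    if denom == 0.0:
        nan_corr = np.full(a.shape, np.nan)
        return (0, 0, 0), float("nan"), nan_corr
    corr = np.real(ifftn(fftn(b0) * np.conj(fftn(a0)))) / denom
    corr = np.fft.fftshift(corr)
    center = np.array([n // 2 for n in corr.shape])
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    shift = tuple(int(p - c) for p, c in zip(peak, center))
    return shift, float(corr[peak]), corr


def subpixel_refine(
    corr: np.ndarray, peak: tuple[int, int, int], method: str = "gaussian"
) -> tuple[np.ndarray, bool]:
    """Refine an integer correlation peak to a fractional offset.

    Fits, per axis, a parabola (``quadratic``) or a log-parabola
    (``gaussian``) through the peak value and its two neighbours. The vertex
    of ``(y-, y0, y+)`` lies at ``(y- - y+) / (2 (y- - 2 y0 + y+))``. Offsets
    are clipped to (-1, 1); a non-concave triple yields offset 0 on that
    axis and a raised warning flag.
    """
    offsets = np.zeros(3)
    warned = False
    for ax in range(3):
        idx = list(peak)
        triple = []
        ok = True
        for d in (-1, 0, 1):
            idx[ax] = peak[ax] + d
            if not 0 <= idx[ax] < corr.shape[ax]:
                ok = False
                break
            triple.append(corr[tuple(idx)])
        if not ok:
            warned = True
            continue
        ym, y0, yp = triple
        if method == "gaussian":
            if ym <= 0 or y0 <= 0 or yp <= 0:
                # Gaussian fit needs positive values; fall back to quadratic
                pass
            else:
                ym, y0, yp = np.log(ym), np.log(y0), np.log(yp)
        denom = ym - 2.0 * y0 + yp
        if denom >= 0 or y0 < max(ym, yp):
            offsets[ax] = 0.0
            warned = True
            continue
        offsets[ax] = float(np.clip((ym - yp) / (2.0 * denom), -0.999, 0.999))
    return offsets, warned


def ncc_search(search: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Zero-normalized cross-correlation of a template over a search region.

    Returns the NCC value for every placement of ``template`` fully inside
    ``search`` (shape ``search.shape - template.shape + 1``). Direct
    evaluation over the small lag set via a BLAS matrix product; placements
    where either window is constant get score 0.
    """
    t = np.asarray(template, dtype=float)
    s = np.asarray(search, dtype=float)
    if any(ss < ts for ss, ts in zip(s.shape, t.shape)):
        raise ValueError("search region smaller than template")
    t0 = t - t.mean()
    t_norm = np.sqrt((t0**2).sum())
    n = t.size
    wins = sliding_window_view(s, t.shape)
    lag_shape = wins.shape[:3]
    flat = wins.reshape(-1, n)
    num = flat @ t0.ravel()
    w_sum = flat.sum(axis=1)
    w_sq = (flat**2).sum(axis=1)
    var = np.maximum(w_sq - w_sum**2 / n, 0.0)
    den = np.sqrt(var) * t_norm
    with np.errstate(invalid="ignore", divide="ignore"):
        ncc = np.where(den > 0, num / den, 0.0)
    return np.clip(ncc, -1.0, 1.0).reshape(lag_shape)


def run_dvc(
    ref: VoxelVolume, deformed: VoxelVolume, params: DvcParams | None = None
) -> DisplacementField:
    """Full subset DVC between two congruent volumes.

    Nodes are placed on a regular grid with ``grid_spacing`` pitch, inset so
    every subset lies inside the volume. Displacements are reported in μm
    (voxel shifts scaled by the anisotropic voxel size) at the physical node
    positions.
    """
    params = params or DvcParams()
    if ref.shape != deformed.shape:
        raise ValueError(f"volume shapes differ: {ref.shape} vs {deformed.shape}")
    if not np.allclose(ref.voxel_size, deformed.voxel_size):
        raise ValueError("volumes have different voxel sizes")
    half = params.subset_size // 2
    inset = half + params.search_margin  # zero-shift search windows fit the volume
    centers = [
        np.arange(inset, n - inset, params.grid_spacing) for n in ref.shape
    ]
    if any(len(c) == 0 for c in centers):
        raise ValueError("volume too small for the requested subset size")
    shape = tuple(len(c) for c in centers)
    u_vox = np.zeros(shape + (3,))  # (z, y, x) voxel shifts
    score = np.zeros(shape)
    valid = np.zeros(shape, dtype=bool)

    vol_shape = np.array(ref.shape)
    margin = params.search_margin

    def window(vol: np.ndarray, c: np.ndarray) -> np.ndarray:
        return vol[
            c[0] - half : c[0] + half + 1,
            c[1] - half : c[1] + half + 1,
            c[2] - half : c[2] + half + 1,
        ]

    for iz, cz in enumerate(centers[0]):
        for iy, cy in enumerate(centers[1]):
            for ix, cx in enumerate(centers[2]):
                node = np.array([cz, cy, cx])
                template = window(ref.data, node)
                # pass 1: coarse integer shift from circular correlation
                shift, sc, _ = correlate_subset(template, window(deformed.data, node))
                if not np.isfinite(sc):
                    continue
                # pass 2: NCC of the template against a search region of the
                # deformed volume around the shifted position
                t_corner = node - half
                expected = node + np.array(shift) - half
                if np.any(expected < 0) or np.any(expected + params.subset_size > vol_shape):
                    # the displaced subset has partly left the volume; no
                    # uncontaminated match exists for this node
                    continue
                s_corner = np.clip(
                    node + np.array(shift) - half - margin, 0, vol_shape - params.subset_size
                )
                s_stop = np.clip(
                    node + np.array(shift) + half + margin + 1,
                    s_corner + params.subset_size,
                    vol_shape,
                )
                search = deformed.data[
                    s_corner[0] : s_stop[0], s_corner[1] : s_stop[1], s_corner[2] : s_stop[2]
                ]
                ncc = ncc_search(search, template)
                peak = np.unravel_index(np.argmax(ncc), ncc.shape)
                sc = float(ncc[peak])
                score[iz, iy, ix] = sc
                if sc < params.min_correlation:
                    continue
                if any(p == 0 or p == s - 1 for p, s in zip(peak, ncc.shape)):
                    # peak on the boundary of the searched lag range: the true
                    # optimum may lie outside and cannot be sub-voxel refined
                    continue
                frac, _ = subpixel_refine(ncc, peak, params.subpixel_method)
                u_vox[iz, iy, ix] = (np.array(peak) + s_corner - t_corner) + frac
                valid[iz, iy, ix] = True

    n_valid = int(valid.sum())
    if n_valid < 8:
        raise ValueError(
            f"insufficient texture: only {n_valid} subsets exceeded the "
            f"correlation threshold {params.min_correlation}"
        )

    # drop boundary node layers with no valid measurement at all (typically
    # where the search window leaves the volume): they carry no information
    # and would otherwise contaminate smoothing and strain stencils
    keep = tuple(
        slice(int(np.argmax(axis_any)), len(axis_any) - int(np.argmax(axis_any[::-1])))
        for axis_any in (
            valid.any(axis=(1, 2)),
            valid.any(axis=(0, 2)),
            valid.any(axis=(0, 1)),
        )
    )
    centers = [c[k] for c, k in zip(centers, keep)]
    u_vox = u_vox[keep[0], keep[1], keep[2]]
    score = score[keep[0], keep[1], keep[2]]
    valid = valid[keep[0], keep[1], keep[2]]

    u_vox = _replace_outliers(u_vox, valid, params)
    if params.smooth_window and params.smooth_window > 1:
        u_vox = _smooth_valid(u_vox, valid, params.smooth_window)

    if params.subtract_rigid:
        med = np.median(u_vox[valid], axis=0)
        u_vox = u_vox - med

    dz, dy, dx = ref.voxel_size
    return DisplacementField(
        z_um=centers[0] * dz,
        y_um=centers[1] * dy,
        x_um=centers[2] * dx,
        ux=u_vox[..., 2] * dx,
        uy=u_vox[..., 1] * dy,
        uz=u_vox[..., 0] * dz,
        score=score,
        valid=valid,
    )


def _smooth_valid(u_vox: np.ndarray, valid: np.ndarray, window: int) -> np.ndarray:
    """Local-linear (Savitzky–Golay) smoothing of the displacement field.

    Measurement noise on individual nodes is amplified by the downstream
    strain differentiation, so each component is smoothed separably along
    every axis with a first-order Savitzky–Golay filter. A local linear fit
    reproduces affine fields exactly — including at the grid boundary,
    where the surface traction is read — so rigid motions and uniform
    strains pass through unchanged. Invalid nodes are first filled with a
    local median so they do not contaminate their neighbours.
    """
    from scipy.signal import savgol_filter

    if window % 2 == 0:
        window += 1
    out = u_vox.copy()
    for c in range(3):
        comp = u_vox[..., c]
        if not valid.all():
            masked = np.where(valid, comp, np.nan)
            med = ndimage.generic_filter(masked, np.nanmedian, size=3, mode="nearest")
            comp = np.where(valid, comp, np.where(np.isfinite(med), med, 0.0))
        for ax in range(3):
            w = min(window, comp.shape[ax] - (comp.shape[ax] + 1) % 2)  # largest odd <= shape
            if w >= 3:
                comp = savgol_filter(comp, w, polyorder=1, axis=ax, mode="interp")
        out[..., c] = comp
    return out


def _replace_outliers(
    u_vox: np.ndarray, valid: np.ndarray, params: DvcParams
) -> np.ndarray:
    """Replace valid nodes that deviate from their local median by > tol voxels.

    Invalid nodes are excluded from the median by NaN-masking; nodes whose
    entire neighbourhood is invalid are left untouched.
    """
    w = params.outlier_median_window
    out = u_vox.copy()
    for c in range(3):
        comp = np.where(valid, u_vox[..., c], np.nan)
        med = ndimage.generic_filter(comp, np.nanmedian, size=w, mode="nearest")
        resid = np.abs(u_vox[..., c] - med)
        bad = valid & np.isfinite(med) & (resid > params.outlier_tol_voxels)
        out[..., c][bad] = med[bad]
    return out
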