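"""Single-cell image quantification.

Mirrors a standard Fiji-style workflow on immunofluorescence z-stacks:
maximum-intensity projection, Otsu segmentation of the actin channel for
the cell outline, particle analysis of the focal-adhesion channel inside
the cell ROI, Pearson colocalization restricted to a mask, and the
background-corrected YAP nuclear:cytosolic sum-intensity ratio.

All 2D measurements operate on maximum-intensity projections; areas are in
μm² via the pixel size, intensities in arbitrary fluorescence units.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from skimage import measure

__all__ = [
    "CellMetrics",
    "RegionSet",
    "max_intensity_project",
    "otsu_threshold",
    "otsu_segment",
    "measure_cell",
    "analyze_fa_particles",
    "pearson_colocalization",
    "yap_nc_ratio",
    "quantify_cell",
]


@dataclass
class RegionSet:
    """Labelled particles from one channel: label image plus per-label stats."""

    labels: np.ndarray  # integer label image, 0 = background
    areas_um2: list[float]
    sum_intensities: list[float]
    channel: str = ""

    @property
    def count(self) -> int:
        return len(self.areas_um2)


@dataclass
class CellMetrics:
    """Per-cell quantification record."""

    cell_area_um2: float
    integrated_actin_intensity: float
    fa_count: int
    fa_areas_um2: list[float] = dc_field(default_factory=list)
    pearson_r: float = float("nan")
    yap_nc_ratio: float = float("nan")


def max_intensity_project(stack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over the leading (z) axis; 2D input passes through."""
    stack = np.asarray(stack)
    if stack.ndim == 2:
        return stack
    if stack.ndim != 3 or stack.shape[0] < 1:
        raise ValueError(f"expected a (nz, ny, nx) stack, got shape {stack.shape}")
    return stack.max(axis=0)


def otsu_threshold(image: np.ndarray, nbins: int = 256) -> float:
    """Histogram threshold maximizing between-class variance.

    Integer images use one bin per grey level; float images are binned into
    ``nbins`` equal-width bins. On a plateau of equal between-class variance
    the lowest threshold is returned. The threshold is exclusive: foreground
    is ``image > threshold``.
    """
    image = np.asarray(image)
    vals = image.ravel()
    if vals.min() == vals.max():
        raise ValueError("degenerate histogram: image is constant")
    if np.issubdtype(image.dtype, np.integer):
        lo, hi = int(vals.min()), int(vals.max())
        counts = np.bincount((vals - lo).astype(np.int64), minlength=hi - lo + 1)
        centers = np.arange(lo, hi + 1, dtype=float)
    else:
        counts, edges = np.histogram(vals, bins=nbins)
        centers = (edges[:-1] + edges[1:]) / 2.0
    counts = counts.astype(float)
    w0 = np.cumsum(counts)[:-1]
    w1 = counts.sum() - w0
    m = np.cumsum(counts * centers)
    mu0 = m[:-1] / np.where(w0 > 0, w0, 1.0)
    mu1 = (m[-1] - m[:-1]) / np.where(w1 > 0, w1, 1.0)
    var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[(w0 == 0) | (w1 == 0)] = -np.inf
    idx = int(np.argmax(var_between))  # argmax takes the first (lowest) on ties
    return float(centers[idx])


def otsu_segment(image: np.ndarray, nbins: int = 256) -> np.ndarray:
    """Binary mask of pixels above the Otsu threshold."""
    return np.asarray(image) > otsu_threshold(image, nbins=nbins)


def measure_cell(
    actin_mip: np.ndarray, mask: np.ndarray, pixel_size_um: float
) -> tuple[float, float]:
    """Projected cell area (μm²) and integrated actin intensity over the ROI."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty cell mask")
    area = float(mask.sum()) * pixel_size_um**2
    integrated = float(np.asarray(actin_mip, dtype=float)[mask].sum())
    return area, integrated


def analyze_fa_particles(
    fa_mip: np.ndarray,
    cell_mask: np.ndarray,
    pixel_size_um: float,
    size_range_um2: tuple[float, float] = (0.1, 15.0),
) -> RegionSet:
    """Threshold, label and size-filter focal-adhesion puncta in the cell ROI.

    Otsu thresholding is computed from intensities inside the cell mask
    only, components are 8-connected, and components whose area falls
    outside ``size_range_um2`` are discarded. An image with no surviving
    component returns an empty RegionSet rather than raising.
    """
    fa_mip = np.asarray(fa_mip, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    thr = otsu_threshold(fa_mip[cell_mask])
    fg = (fa_mip > thr) & cell_mask
    labels = measure.label(fg, connectivity=2)
    lo, hi = size_range_um2
    px_area = pixel_size_um**2
    out = np.zeros_like(labels)
    areas: list[float] = []
    sums: list[float] = []
    next_label = 0
    for region in measure.regionprops(labels, intensity_image=fa_mip):
        area = region.area * px_area
        if not lo <= area <= hi:
            continue
        next_label += 1
        out[labels == region.label] = next_label
        areas.append(float(area))
        sums.append(float(region.image_intensity[region.image].sum()))
    return RegionSet(labels=out, areas_um2=areas, sum_intensities=sums, channel="fa")


def pearson_colocalization(
    ch1: np.ndarray, ch2: np.ndarray, mask: np.ndarray
) -> float:
    """Pearson correlation of paired pixel intensities restricted to a mask.

    A constant channel inside the mask makes the coefficient undefined;
    that case returns NaN rather than raising, so batch pipelines can flag
    and continue.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("mask must contain at least 3 pixels")
    a = np.asarray(ch1, dtype=float)[mask]
    b = np.asarray(ch2, dtype=float)[mask]
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(np.clip(r, -1.0, 1.0))


def yap_nc_ratio(
    yap_mip: np.ndarray,
    nuc_mask: np.ndarray,
    cyto_mask: np.ndarray,
    bg_roi: np.ndarray,
) -> float:
    """Background-corrected nuclear:cytosolic YAP sum-intensity ratio.

    ``ratio = (sum_nuc - b * A_nuc) / (sum_cyto - b * A_cyto)`` where ``b``
    is the mean intensity in the background ROI and ``A`` the region pixel
    counts: the measured mean background is scaled to each region's area
    before subtraction from the summed intensities. A non-positive
    denominator yields NaN.
    """
    yap = np.asarray(yap_mip, dtype=float)
    nuc = np.asarray(nuc_mask, dtype=bool)
    cyto = np.asarray(cyto_mask, dtype=bool)
    bg = np.asarray(bg_roi, dtype=bool)
    if not nuc.any() or not cyto.any() or not bg.any():
        raise ValueError("nuclear, cytosolic and background ROIs must be nonempty")
    if (nuc & cyto).any():
        raise ValueError("nuclear and cytosolic masks overlap")
    b_mean = yap[bg].mean()
    num = yap[nuc].sum() - b_mean * nuc.sum()
    den = yap[cyto].sum() - b_mean * cyto.sum()
    if den <= 0:
        return float("nan")
    return float(num / den)


def quantify_cell(
    channels: dict[str, np.ndarray],
    pixel_size_um: float,
    size_range_um2: tuple[float, float] = (0.1, 15.0),
    coloc_channels: tuple[str, str] | None = None,
) -> CellMetrics:
    """End-to-end quantification of one multi-channel cell image.

    Projects each channel (if 3D), segments the cell from actin, counts FA
    particles within the cell ROI, computes the YAP nuclear:cytosolic ratio
    (nucleus from DAPI, cytosol = cell minus nucleus, background = the
    image outside a dilated cell mask) and, when ``coloc_channels`` names
    two channels, their Pearson coefficient inside the segmented FA mask.
    """
    from scipy import ndimage

    mips = {name: max_intensity_project(img) for name, img in channels.items()}
    if "actin" not in mips:
        raise ValueError("actin channel is required for cell segmentation")
    cell_mask = otsu_segment(mips["actin"])
    area, actin_int = measure_cell(mips["actin"], cell_mask, pixel_size_um)

    fa_count, fa_areas = 0, []
    regions = None
    if "fa" in mips:
        regions = analyze_fa_particles(mips["fa"], cell_mask, pixel_size_um, size_range_um2)
        fa_count, fa_areas = regions.count, regions.areas_um2

    metrics = CellMetrics(
        cell_area_um2=area,
        integrated_actin_intensity=actin_int,
        fa_count=fa_count,
        fa_areas_um2=fa_areas,
    )

    if "yap" in mips and "dapi" in mips:
        nuc_mask = otsu_segment(mips["dapi"])
        cyto_mask = cell_mask & ~nuc_mask
        bg_roi = ~ndimage.binary_dilation(cell_mask | nuc_mask, iterations=5)
        if bg_roi.any() and cyto_mask.any():
            metrics.yap_nc_ratio = yap_nc_ratio(mips["yap"], nuc_mask, cyto_mask, bg_roi)

    if coloc_channels is not None:
        c1, c2 = coloc_channels
        if regions is None:
            raise ValueError("colocalization requires the fa channel mask")
        fa_mask = regions.labels > 0
        if fa_mask.sum() >= 3:
            metrics.pearson_r = pearson_colocalization(mips[c1], mips[c2], fa_mask)
    return metrics
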