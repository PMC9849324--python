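"""Seeded generators of ground-truthed synthetic inputs.

Two families of fixtures are produced here:

* **Bead-seeded gel volumes** emulating the before/after-relaxation
  fluorescent-bead z-stacks of 3D traction force microscopy: sub-resolution
  beads rendered as 3D Gaussians in an anisotropic voxel grid, optionally
  warped by an analytic displacement field and corrupted by noise.
* **Multi-channel single-cell images** with a prescribed cell outline,
  peripheral actin texture, a known number of well-separated focal-adhesion
  puncta, a DAPI nucleus and a YAP channel with a prescribed
  nuclear:cytosolic mean-intensity ratio.

Every scene carries its ground truth so each downstream stage can be tested
as a recovery problem. All randomness flows from the single seed stored in
the config; identical configs produce bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .core import GelModel, VoxelVolume
from .fields import evaluate_displacement

__all__ = [
    "SceneConfig",
    "CellSceneConfig",
    "GroundTruth",
    "CellGroundTruth",
    "generate_bead_volume",
    "deform_volume",
    "make_scene_pair",
    "generate_cell_image",
]


@dataclass
class SceneConfig:
    """Configuration of a synthetic bead-gel volume.

    Defaults describe a 25.6 μm cube sampled anisotropically
    (64 × 128 × 128 voxels at 0.4 × 0.2 × 0.2 μm), seeded densely enough
    that a 17-voxel correlation subset contains several beads.
    """

    rng_seed: int = 0
    volume_shape: tuple[int, int, int] = (64, 128, 128)  # (nz, ny, nx)
    voxel_size: tuple[float, float, float] = (0.4, 0.2, 0.2)  # (dz, dy, dx) μm
    bead_density: float = 0.08  # beads per μm³
    # effective bead image width (bead ⊗ PSF) per axis, μm; confocal PSFs are
    # axially elongated, so (σz, σy, σx) with σz ≈ 2 σxy; a scalar is isotropic
    bead_sigma_um: float | tuple[float, float, float] = (0.5, 0.25, 0.25)
    noise_sd: float = 0.02  # Gaussian read noise, fraction of unit bead peak
    poisson_noise: bool = False
    displacement_spec: Mapping | None = None
    gel: GelModel = dc_field(default_factory=lambda: GelModel(young_modulus_kpa=14.0))
    bead_positions_um: np.ndarray | None = None  # explicit (n,3) (z,y,x) centres; skips random seeding

    def __post_init__(self) -> None:
        if any(n < 16 for n in self.volume_shape):
            raise ValueError(f"volume_shape axes must all be >= 16, got {self.volume_shape}")
        if np.isscalar(self.bead_sigma_um):
            self.bead_sigma_um = (float(self.bead_sigma_um),) * 3
        self.bead_sigma_um = tuple(float(s) for s in self.bead_sigma_um)
        if any(s <= 0 for s in self.bead_sigma_um):
            raise ValueError("bead_sigma_um must be positive")
        if self.bead_density <= 0:
            raise ValueError("bead_density must be positive")

    @property
    def extent_um(self) -> tuple[float, float, float]:
        return tuple(n * d for n, d in zip(self.volume_shape, self.voxel_size))

    @property
    def domain_volume_um3(self) -> float:
        ez, ey, ex = self.extent_um
        return ez * ey * ex


@dataclass
class GroundTruth:
    """What a bead scene actually contains, for recovery tests."""

    bead_positions_um: np.ndarray  # (n, 3) as (z, y, x)
    displacement_spec: Mapping | None
    gel: GelModel


def generate_bead_volume(config: SceneConfig) -> tuple[VoxelVolume, GroundTruth]:
    """Render a bead-seeded gel volume.

    The bead count is Poisson with mean ``density × domain volume``, bead
    centres are uniform over the domain, and each bead is a unit-amplitude
    isotropic 3D Gaussian of physical width ``bead_sigma_um`` rendered into
    the anisotropic voxel grid. Gaussian read noise of ``noise_sd`` (and
    optionally Poisson shot noise) is added last.
    """
    rng = np.random.default_rng(config.rng_seed)
    if config.bead_positions_um is not None:
        positions = np.asarray(config.bead_positions_um, dtype=float).reshape(-1, 3)
    else:
        n_beads = int(rng.poisson(config.bead_density * config.domain_volume_um3))
        if n_beads < 10:
            raise ValueError(
                f"configuration yields only {n_beads} beads (< 10); volume correlation "
                "would be untestable — raise bead_density or enlarge the volume"
            )
        extent = np.array(config.extent_um)
        positions = rng.uniform(0.0, 1.0, size=(n_beads, 3)) * extent
    data = _render_beads(positions, config)
    data = _add_noise(data, config, acquisition=0)
    vol = VoxelVolume(data=data, voxel_size=config.voxel_size)
    return vol, GroundTruth(
        bead_positions_um=positions,
        displacement_spec=config.displacement_spec,
        gel=config.gel,
    )


def _add_noise(data: np.ndarray, config: SceneConfig, acquisition: int) -> np.ndarray:
    """Per-acquisition camera noise: each imaging pass gets its own stream."""
    rng = np.random.default_rng([config.rng_seed, 7919 + acquisition])
    if config.poisson_noise:
        # shot noise at an arbitrary gain of 100 photons per unit intensity
        gain = 100.0
        data = rng.poisson(np.clip(data, 0, None) * gain) / gain
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
    return data


def make_scene_pair(
    config: SceneConfig, spec: Mapping | None = None
) -> tuple[VoxelVolume, VoxelVolume, GroundTruth]:
    """Reference/deformed acquisition pair with independent camera noise.

    The noiseless bead field is rendered once, warped by the displacement
    spec, and each of the two volumes then receives its own noise
    realization — as in a real experiment, where the relaxed and stressed
    stacks are separate acquisitions. Warping the *noisy* reference instead
    would correlate the noise between the two volumes and bias sub-voxel
    correlation toward integer shifts.
    """
    spec = spec if spec is not None else config.displacement_spec
    if spec is None:
        raise ValueError("a displacement spec is required (in config or argument)")
    from dataclasses import replace

    clean_cfg = replace(config, noise_sd=0.0, poisson_noise=False)
    ref_clean, truth = generate_bead_volume(clean_cfg)
    truth = GroundTruth(
        bead_positions_um=truth.bead_positions_um,
        displacement_spec=spec,
        gel=config.gel,
    )
    deformed_clean = deform_volume(ref_clean, spec)
    ref = VoxelVolume(
        _add_noise(ref_clean.data, config, acquisition=0), config.voxel_size
    )
    deformed = VoxelVolume(
        _add_noise(deformed_clean.data, config, acquisition=1), config.voxel_size
    )
    return ref, deformed, truth


def _render_beads(positions_um: np.ndarray, config: SceneConfig) -> np.ndarray:
    """Additively render unit Gaussians at physical positions, windowed to ±4σ."""
    shape = config.volume_shape
    vox = np.array(config.voxel_size)
    sigma = np.array(config.bead_sigma_um)
    half = np.ceil(4.0 * sigma / vox).astype(int)  # window half-size per axis
    data = np.zeros(shape)
    axis_offsets = [np.arange(-h, h + 1) for h in half]
    for pos in positions_um:
        center_vox = pos / vox
        nearest = np.round(center_vox).astype(int)
        profiles = []
        slices = []
        ok = True
        for ax in range(3):
            idx = nearest[ax] + axis_offsets[ax]
            keep = (idx >= 0) & (idx < shape[ax])
            if not keep.any():
                ok = False
                break
            idx = idx[keep]
            d_um = idx * vox[ax] - pos[ax]
            profiles.append(np.exp(-(d_um**2) / (2.0 * sigma[ax] ** 2)))
            slices.append(slice(idx[0], idx[-1] + 1))
        if not ok:
            continue
        blob = profiles[0][:, None, None] * profiles[1][None, :, None] * profiles[2][None, None, :]
        data[slices[0], slices[1], slices[2]] += blob
    return data


def deform_volume(
    volume: VoxelVolume,
    spec: Mapping,
    *,
    order: int = 3,
    background: float = 0.0,
) -> VoxelVolume:
    """Warp a volume by an analytic displacement field (pull-back convention).

    The deformed image is the reference resampled at ``x - u(x)``: intensity
    that sat at material point ``x - u`` ends up at ``x``, i.e. features move
    *by* ``+u``. Spline interpolation of the given order is used and samples
    falling outside the domain are filled with ``background``.
    """
    if order < 3:
        raise ValueError("interpolation order must be >= 3")
    z_um, y_um, x_um = volume.axis_coords_um()
    zz, yy, xx = np.meshgrid(z_um, y_um, x_um, indexing="ij")
    ux, uy, uz = evaluate_displacement(spec, zz, yy, xx)
    for comp in (ux, uy, uz):
        if not np.all(np.isfinite(comp)):
            raise ValueError("displacement field evaluates to non-finite values")
    max_disp = max(float(np.abs(c).max()) for c in (ux, uy, uz))
    if max_disp >= min(volume.axis_coords_um()[i][-1] + volume.voxel_size[i] for i in range(3)) / 4:
        raise ValueError(
            f"displacement magnitude {max_disp:.3g} μm exceeds a quarter of the domain extent"
        )
    dz, dy, dx = volume.voxel_size
    coords = np.stack(
        [(zz - uz) / dz, (yy - uy) / dy, (xx - ux) / dx]
    )
    warped = ndimage.map_coordinates(
        volume.data, coords, order=order, mode="constant", cval=background, prefilter=True
    )
    return VoxelVolume(data=warped, voxel_size=volume.voxel_size)


# ---------------------------------------------------------------------------
# Single-cell image scenes
# ---------------------------------------------------------------------------


@dataclass
class CellSceneConfig:
    """Configuration of a synthetic multi-channel single-cell image.

    Intensities are arbitrary fluorescence units on a 16-bit-like scale.
    The YAP channel is constructed so that the background-corrected
    nuclear:cytosolic *summed*-intensity ratio — the quantity the
    translocation assay reports — equals ``yap_nc_ratio_true`` exactly
    before noise.
    """

    rng_seed: int = 0
    image_shape: tuple[int, int] = (256, 256)  # (ny, nx)
    pixel_size_um: float = 0.2
    channels: tuple[str, ...] = ("actin", "fa", "dapi", "yap")
    n_fa_puncta: int = 20
    fa_area_um2: float = 1.0  # drawn area of each punctum
    cell_radius_um: float = 15.0
    nuc_radius_um: float = 6.0
    yap_nc_ratio_true: float = 2.0
    background_level: float = 5.0
    noise_sd: float = 0.5  # additive Gaussian noise, intensity units

    def __post_init__(self) -> None:
        if self.nuc_radius_um >= self.cell_radius_um:
            raise ValueError("nucleus must be smaller than the cell")
        if self.yap_nc_ratio_true <= 0:
            raise ValueError("yap_nc_ratio_true must be positive")
        unknown = set(self.channels) - {"actin", "fa", "dapi", "yap", "mcherry"}
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")


@dataclass
class CellGroundTruth:
    cell_mask: np.ndarray
    nuc_mask: np.ndarray
    n_fa_true: int
    fa_centers_px: np.ndarray  # (n, 2) as (row, col)
    fa_area_um2_true: float
    yap_nc_ratio_true: float


# photometry of the noiseless channels (arbitrary units)
_ACTIN_BASE = 60.0
_ACTIN_RING = 70.0
_FA_CYTO_BASE = 20.0
_FA_PUNCTUM_AMP = 150.0
_FA_EDGE_SIGMA_UM = 0.1  # edge softness of a punctum (≈ lateral PSF width)
_DAPI_AMP = 120.0
_YAP_CYTO_MEAN = 40.0


def generate_cell_image(
    config: CellSceneConfig,
) -> tuple[dict[str, np.ndarray], CellGroundTruth]:
    """Draw a single synthetic cell and return channel images plus truth.

    The cell is an ellipse (semi-axes ``cell_radius_um`` × 0.8), the actin
    channel has a bright peripheral band over a uniform interior, the FA
    channel contains exactly ``n_fa_puncta`` soft-edged puncta of prescribed
    area whose centres are pairwise separated by at least three punctum
    diameters, DAPI is a nuclear disk and YAP encodes the prescribed
    nuclear:cytosolic ratio on top of a uniform background.
    """
    rng = np.random.default_rng(config.rng_seed)
    ny, nx = config.image_shape
    px = config.pixel_size_um
    yy, xx = np.mgrid[0:ny, 0:nx] * px
    cy, cx = (ny * px) / 2.0, (nx * px) / 2.0
    a, b = config.cell_radius_um, 0.8 * config.cell_radius_um  # x, y semi-axes
    r2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    cell_mask = r2 <= 1.0
    nuc_mask = ((xx - cx) ** 2 + (yy - cy) ** 2) <= config.nuc_radius_um**2

    channels: dict[str, np.ndarray] = {}
    bg = config.background_level

    if "actin" in config.channels:
        # peripheral band: Gaussian in the normalized radial coordinate
        ring = np.exp(-((np.sqrt(r2) - 0.85) ** 2) / (2 * 0.08**2))
        actin = np.full((ny, nx), bg)
        actin[cell_mask] = bg + _ACTIN_BASE + _ACTIN_RING * ring[cell_mask]
        channels["actin"] = actin

    fa_centers = np.zeros((0, 2))
    if "fa" in config.channels:
        fa, fa_centers = _draw_fa_channel(config, cell_mask, rng)
        channels["fa"] = fa

    if "dapi" in config.channels:
        dapi = np.full((ny, nx), bg)
        dapi[nuc_mask] = bg + _DAPI_AMP
        channels["dapi"] = dapi

    if "yap" in config.channels:
        # the assay divides background-corrected *summed* intensities, so the
        # prescribed ratio fixes sum_nuc/sum_cyto, not the mean ratio
        yap = np.full((ny, nx), bg)
        cyto = cell_mask & ~nuc_mask
        yap[cyto] = bg + _YAP_CYTO_MEAN
        nuc_mean = _YAP_CYTO_MEAN * config.yap_nc_ratio_true * cyto.sum() / nuc_mask.sum()
        yap[nuc_mask] = bg + nuc_mean
        channels["yap"] = yap

    if "mcherry" in config.channels:
        mch = np.full((ny, nx), bg)
        mch[cell_mask] = bg + 50.0
        channels["mcherry"] = mch

    if config.noise_sd > 0:
        for name in channels:
            channels[name] = channels[name] + rng.normal(
                0.0, config.noise_sd, size=(ny, nx)
            )

    truth = CellGroundTruth(
        cell_mask=cell_mask,
        nuc_mask=nuc_mask,
        n_fa_true=len(fa_centers),
        fa_centers_px=fa_centers,
        fa_area_um2_true=config.fa_area_um2,
        yap_nc_ratio_true=config.yap_nc_ratio_true,
    )
    return channels, truth


def _draw_fa_channel(
    config: CellSceneConfig, cell_mask: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Place well-separated puncta of known area inside the cell mask.

    Each punctum is a disk of area ``fa_area_um2`` with a lightly
    Gaussian-smoothed edge, so that the area recovered by any threshold in
    the middle of the intensity range matches the drawn area. Centres are
    drawn by rejection sampling with a minimum pairwise separation of three
    punctum diameters and a margin from the cell edge.
    """
    ny, nx = config.image_shape
    px = config.pixel_size_um
    radius_um = math.sqrt(config.fa_area_um2 / math.pi)
    diameter_um = 2.0 * radius_um
    min_sep_px = 3.0 * diameter_um / px

    # candidate pixels: inside the cell, away from the edge so puncta stay inside
    margin_px = int(np.ceil((radius_um + 3.0 * _FA_EDGE_SIGMA_UM) / px))
    interior = ndimage.binary_erosion(cell_mask, iterations=max(margin_px, 1))
    cand = np.argwhere(interior)
    if len(cand) == 0:
        raise ValueError("cell interior too small to place focal-adhesion puncta")

    centers: list[np.ndarray] = []
    max_tries = 200 * max(config.n_fa_puncta, 1)
    for _ in range(max_tries):
        if len(centers) == config.n_fa_puncta:
            break
        c = cand[rng.integers(len(cand))] + rng.uniform(-0.5, 0.5, size=2)
        if all(np.hypot(*(c - o)) >= min_sep_px for o in centers):
            centers.append(c)
    if len(centers) < config.n_fa_puncta:
        raise ValueError(
            f"could not place {config.n_fa_puncta} puncta with the required "
            f"separation after {max_tries} tries; lower n_fa_puncta or fa_area_um2"
        )

    fa = np.full((ny, nx), config.background_level)
    fa[cell_mask] += _FA_CYTO_BASE
    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    r_px = radius_um / px
    edge_px = _FA_EDGE_SIGMA_UM / px
    for cyx in centers:
        d = np.hypot(yy - cyx[0], xx - cyx[1])
        win = d <= r_px + 5.0 * edge_px
        # smooth-edged disk: ~1 inside, ~0 outside, half-height at r_px
        profile = 0.5 * (1.0 - np.tanh((d[win] - r_px) / (math.sqrt(2.0) * edge_px)))
        fa[win] += _FA_PUNCTUM_AMP * profile
    return fa, np.array(centers)
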