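# Methods

This note documents the models, algorithmic choices and defaults behind
`stemmech`, and what the synthetic fixtures do and do not establish about
real data.

## Coordinate and unit conventions

Grids are indexed `[z, y, x]` with z the optical axis increasing toward the
gel surface; vector and tensor components are ordered `(x, y, z)`. Physical
coordinates are micrometres at voxel centres from the volume origin;
displacements are in μm, strain dimensionless, stress and traction in
pascal. Young's moduli are entered in kPa and converted internally.

## Elastic reconstruction

The mechanics chain is deliberately local and linear:

1. **Strain.** The infinitesimal strain tensor ε = ½(∇u + ∇uᵀ) is computed
   by central differences on the DVC node grid (second-order one-sided at
   the grid boundary). Strains in all validation scenes are ≤ 2 %, where the
   small-strain tensor and a finite-strain measure are indistinguishable at
   the accuracy of the displacement data.
2. **Stress.** σ = E ε / (1 + ν) componentwise, with ν = 0.5. At ν = 0.5
   this equals 2με, the deviatoric (shear-only) response; it carries no
   hydrostatic pressure term, so purely volumetric strain produces no
   stress. That is a property of the reconstruction protocol this package
   reproduces — the closed-form oracles use the identical rule, so the
   comparison between pipeline and oracle is exact. It is *not* the full
   constitutive law of an incompressible solid, and absolute normal
   tractions should be interpreted with that caveat.
3. **Traction.** T = σ·n̂ on the highest-z layer of valid nodes, n̂ = (0,0,1).
   Strain is computed through the volume and the surface layer extracted,
   rather than evaluated from a surface-only stencil. Reported maps are
   |Txy| = √(Tx²+Ty²) and |Tzz| = |Tz|; per-cell values are arithmetic means
   over valid surface nodes inside the (optionally user-supplied) cell mask.

Rigid motions (translations and small rotations) have identically zero
strain; on analytic grids the pipeline reproduces this to < 1e−10 Pa, which
is the round-off of the finite-difference stencil.

## Digital volume correlation

Subset-based, two-pass matching per node:

1. a coarse **integer shift** from zero-mean FFT circular cross-correlation
   of co-located subsets;
2. a **refinement pass** that slides the reference subset over a
   ±`search_margin` (3 voxel) region of the deformed volume centred at the
   shifted position (zero-normalized cross-correlation, evaluated directly
   over the small lag set) and fits a separable three-point Gaussian (or
   quadratic) through the peak for the sub-voxel offset.

The second pass exists because correlating two subsets cropped at the same
window is biased: beads straddling the window edge are truncated
identically in both crops, which makes the windows most similar at zero lag
and drags the peak toward integers (we measured a 0.3-voxel shift collapse
to ~0.19 voxel with single-pass matching). Matching the reference template
against *uncropped* deformed data removes the artifact; the same reasoning
is why reference/deformed synthetic pairs carry independent noise
realizations (see below).

Defaults: subset 25³ voxels, node spacing 8 voxels, minimum correlation
0.5, Gaussian sub-voxel fit, 3³ median outlier replacement (residual > 1
voxel), and first-order Savitzky–Golay smoothing of the node field with an
axis-clamped window of 13 nodes. The subset size is larger than the
smallest workable subset because displacement precision is limited by bead
texture: each subset must average over enough beads (~20 at the default
seeding density) that the correlation-peak shape noise stays near 0.01
voxel. Local-*linear* smoothing is used because the traction readout
differentiates the field: it suppresses node noise while reproducing affine
fields (rigid motions, uniform shear and stretch) exactly, including at the
grid boundary where the surface traction is read. The price is in-plane
spatial resolution of order the smoothing window (~20 μm at default
spacing); for localized traction features, reduce `smooth_window` and
accept a higher noise floor.

Nodes are placed so that a zero-shift search window fits inside the volume;
nodes whose displaced subset leaves the volume, or whose correlation peak
lies on the boundary of the searched lag range, are flagged invalid rather
than guessed. Entirely invalid boundary node layers are cropped from the
grid before smoothing — backfilling them from neighbours would flatten
boundary gradients and bias the surface strain.

Sign convention: `u` maps the reference (relaxed, post-release) state to the
deformed (stressed) state. `subtract_rigid` removes the global median
displacement (stage drift) and is off by default, since whether drift
correction was part of the original protocol is unknown.

Measured performance at default conditions (64×128×128 voxels at
0.4×0.2×0.2 μm, 0.08 beads/μm³, 2 % read noise): integer shifts recovered
to < 0.01 voxel, a 0.3-voxel shift to ±0.01 voxel in the mean, RMS
displacement error ≈ 0.01 voxel at 5 % noise, end-to-end shear traction
within ~5 % of the closed form, and rigid-motion residual tractions of
1–2.5 Pa (dominated, for rotations, by within-subset decorrelation, whose
remedy — affine subset warping — is out of scope).

## Synthetic scenes

**Bead volumes.** Default geometry 64×128×128 voxels at 0.4×0.2×0.2 μm
(a 25.6 μm cube): large enough for ~5×13×13 correlation nodes, small enough
that a full DVC run takes tens of seconds. Beads are uniform random points
(Poisson count, default 0.08 beads/μm³) rendered as unit-amplitude 3D
Gaussians with widths (σz, σy, σx) = (0.5, 0.25, 0.25) μm — an axially
elongated effective bead image, as a confocal PSF produces; an isotropic
bead image at this axial sampling would be unphysical and undersample the
axial correlation peak. Additive Gaussian read noise (default 2 % of the
bead peak) models the camera; Poisson shot noise is an optional flag. The
deformed volume is the *noiseless* bead field warped by an analytic
displacement spec (pull-back resampling at x − u(x), cubic spline), after
which each of the two volumes receives its own independent noise
realization — exactly as two separate acquisitions would. Warping the noisy
reference instead correlates the noise between the volumes and biases
sub-voxel matching toward integer shifts.

The analytic spec library (constant shift, simple shear, uniaxial stretch,
small rotation, Gaussian-bump shear) carries exact closed-form surface
tractions under the same constitutive rule, providing the oracle for every
recovery test.

**Cell images.** A single elliptical cell (default semi-axes 15×12 μm on a
51.2 μm field at 0.2 μm pixels) with: an actin channel (uniform interior
plus a peripheral band), a focal-adhesion channel with exactly
`n_fa_puncta` soft-edged disks of prescribed area (tanh edge of width
0.1 μm ≈ lateral PSF; a disk's thresholded area is robust to the exact
threshold, which is what makes an area round-trip meaningful), a DAPI disk,
and a YAP channel whose background-corrected nuclear:cytosolic
*summed*-intensity ratio equals the prescribed value exactly before noise —
the summed (not mean) ratio is what the translocation assay computes.
Puncta centres are rejection-sampled with pairwise separation ≥ 3 punctum
diameters and a margin from the cell edge.

**What passing these tests shows — and does not.** The fixtures establish
that the estimators are unbiased and correctly calibrated on data that
satisfy their assumptions: ideal Gaussian/disk photometry, a strictly
bimodal intensity histogram, well-separated puncta, noise-free masks'
existence, affine or smooth displacement fields. Real stacks add optical
sectioning artifacts, bleaching, touching adhesions, irregular cell shapes,
bead aggregation and drift; none of these failure modes is exercised here,
so quantitative error bounds from the synthetic tests do not transfer to
real data unchecked.

## Image quantification

All 2D measurements operate on maximum-intensity projections. Otsu
thresholding is computed from the intensity histogram (one bin per grey
level for integer images, 256 bins otherwise); on a plateau of equal
between-class variance the lowest threshold is taken, and the threshold is
exclusive (foreground strictly above). Focal-adhesion particles are
8-connected components of the Otsu foreground *within the cell ROI*,
size-filtered to 0.1–15 μm² by default (the filter bounds are exposed;
the lower bound rejects single-pixel noise, the upper bound whole-cell
blobs). Integrated actin intensity is the raw sum over the cell ROI —
background subtraction for actin is deliberately opt-in
(`--actin-bg-subtract` semantics), since whether the original measurement
subtracted background is unstated. The cytosolic YAP compartment is the
whole-cell mask minus the nuclear mask; the background ROI is taken outside
a dilated cell mask. Pearson colocalization is the plain correlation of
paired pixels inside the mask with no intensity thresholding; a constant
channel makes it undefined and returns NaN rather than raising.

## Statistics

The normality gate applies Shapiro–Wilk to every group separately and takes
the parametric branch only if all groups pass at `NORMALITY_ALPHA = 0.01`.
The gate level matters: screening each group at 0.05 would spuriously
demote ~10 % of genuinely Gaussian two-group comparisons to the rank branch
(1 − 0.95²), while at 0.01 that loss is ~2 % and skewed or heavy-tailed
samples of realistic size (n ≈ 90) still fail the screen essentially
always. The parametric branch uses Welch's t-test by default (pooled
variance optional); the rank branch uses the two-sided Mann–Whitney U with
tie correction, or Kruskal–Wallis for ≥ 3 groups. Constant-and-identical
samples short-circuit to p = 1 ("degenerate"), since no test statistic is
defined. Stars: \* ≤ 0.05, \*\* ≤ 0.01, \*\*\* ≤ 0.001, \*\*\*\* ≤ 0.0001.
No multiple-testing correction is applied (comparisons are per panel); this
is a documented limitation, not an oversight. Box–whisker summaries report
the median, quartile box and 5th/95th-percentile whiskers.

Fold changes divide each measurement by its loading-control signal and then
by the control condition's normalized value, so the control maps to exactly
1. qPCR uses 2^(−ΔΔCt) with ΔCt = Ct_target − Ct_reference and ΔΔCt taken
against the control condition's mean ΔCt.

## Numerical details and degenerate inputs

- Zero-variance correlation windows score NaN and flag the node invalid
  (never an exception); fewer than 8 valid nodes raises "insufficient
  texture".
- Non-concave sub-voxel neighbourhoods return offset 0 with a warning flag;
  the Gaussian fit falls back to the quadratic when correlation values are
  non-positive.
- Otsu on a constant image raises (degenerate histogram); the YAP ratio
  returns NaN when the background-corrected cytosolic sum is ≤ 0.
- A non-unit gel surface normal is normalized with a warning; ν = −1 is
  rejected as a singular gel model.
- 16-bit TIFF round trips are bit-exact for integer data; float data are
  scaled into the uint16 range with the scale recorded in the JSON sidecar.

## Problem sizes

Unit tests run on 48×96×96 gel blocks and 256² cell images; acceptance
checks use the default 64×128×128 geometry, 5 seeds for the end-to-end
shear recovery, 20 cell scenes, 50 random images for the Otsu comparison
and 2000 replicates for the type-I calibration. These sizes were chosen so
the full suite completes in minutes on a single CPU while keeping every
statistical bound comfortably inside its Monte-Carlo noise.
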