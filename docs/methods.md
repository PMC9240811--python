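# Methods

This note records the models, conventions and numerical choices behind
`fcdtools`, and what the synthetic validation does and does not establish.

## Temporal preprocessing

The pipeline assumes spatially aligned data on one grid (the simulator
emits data that way); only the temporal chain is implemented, in this
order: discard initial volumes → frame-wise displacement → nuisance
regression → band-pass. The order follows the usual narrative of
resting-state protocols: regression precedes filtering, and the spike
regressors are not themselves filtered.

**Volume discard.** Default `n_discard = 10` (signal equilibration), so a
180-volume acquisition leaves 170 analyzed volumes.

**Frame-wise displacement (Jenkinson).** Motion parameters (3 translations
mm, 3 rotations radians; rotations composed Rx·Ry·Rz) define per-volume
rigid transforms `T_i`. With `M = T_i T_{i-1}^{-1} − I`, `A` its 3×3 block
and `b` its translation,

    FD_i = sqrt( (R²/5)·trace(AᵀA) + bᵀb ),  R = 80 mm,  FD_0 = 0.

This is the analytic RMS displacement of a solid sphere of radius 80 mm
under the relative transform; the `R²/5` factor is the solid-ball second
moment (a Monte-Carlo oracle must sample *inside* the ball — surface
sampling would give `R²/3`). The implementation is analytic, not
image-based. Note that FD is exactly invariant to a constant parameter
offset only when the rotation part is constant; with varying rotations the
offset re-enters through the relative rotation (center-of-rotation
dependence). For motion within realistic amplitudes the deviation is at
the percent level, and tests pin both behaviours.

**Nuisance design.** Columns, in order: 6 motion parameters, their backward
differences (first row 0 — the standard convention where the derivative at
the first retained volume is undefined), mean BOLD over the white-matter
mask, mean over the CSF mask, one one-hot column per volume with
FD strictly above 0.5 mm, and an intercept: 15 + (number of spikes)
columns. "Strictly above" implements spike adjustment as
scrubbing-by-regression: deleting volumes would break the uniform sampling
the Fourier filter needs, whereas a one-hot column removes the volume's
influence from every voxel's fit exactly. Tissue masks are caller inputs
and are not eroded; in the synthetic pipeline they are designated
background blocks. Rank-deficient designs are rejected with the offending
columns named.

**Band-pass.** Per voxel: linear detrend (configurable, default on), real
FFT, zero every bin outside `low ≤ f ≤ high` (default 0.01–0.08 Hz,
validated against Nyquist = 1/(2·TR)), inverse FFT. The ideal boxcar
mirrors the common resting-state toolchain behaviour; with 170 volumes at
TR 2 s the bin spacing is ~0.003 Hz, so an in-band sinusoid keeps its
amplitude to within a few percent (the detrend removes a little low-
frequency mass) and DC/stop-band components vanish to machine precision.

## gFCD mapping

Series are demeaned and unit-normalized so that a chunked matrix product
`Z[block] @ Z.T` yields Pearson correlations; each voxel's count is the
number of *other* in-mask voxels with `r > R` (default R = 0.6, one-sided:
anticorrelations never count). Chunking bounds memory (the full V×V matrix
is never held for large V) and must not change results — tests require
exact integer equality with a brute-force per-pair oracle for arbitrary
chunk sizes.

Two boundary rules make the count well defined:

- **Threshold guard.** Connectivity is `r > R + 1e-12`. A strict inequality
  at a real threshold is ill-posed at floating-point resolution (a pair
  whose true correlation is exactly R can round a half-ulp either way); the
  guard is ~10 orders of magnitude below the sampling error of any
  realistic series length, and makes "exactly R is not connected" hold
  robustly.
- **Zero-variance voxels** (constant series, detected by max = min) have
  undefined correlation; they are counted as connected to nothing and
  contribute to no other voxel's count, with a warning.

Smoothing is separable Gaussian convolution with
`sigma = FWHM / (2·sqrt(2·ln2))` per axis, converted to voxel units from
the affine (6 mm on 3 mm voxels → σ = 0.849 voxels), zero-padded at the
boundary and re-masked afterwards. Raw counts are smoothed *after*
computation, never the time series. Hub maps divide each subject's map by
its in-mask mean (so the rescaled mean is exactly 1 — mean-normalization is
the convention adopted for "rescaled"; the source literature does not
define it further) and average within group.

## Group statistics

Voxel-wise OLS of the map value on `[intercept, group, age, gender]`
(patient = 1; gender coded M = 1 — any affine coding gives the same group
t). t = group coefficient / SE with df = n − rank; two-sided p. With no
covariates this reduces *exactly* (1e−10) to the textbook pooled two-sample
t, which the tests use as the oracle. Voxels fitted exactly (residual sum
of squares below 1e−24 of the signal energy, e.g. identical values in both
groups) are defined as t = 0, p = 1 rather than 0/0 noise. The
group-coefficient map is kept as the *effect map* (adjusted mean
difference) alongside t.

FDR is Benjamini–Hochberg within the analysis mask (the correction family
is the mask, matching the mask-restricted computation), computed via
statsmodels; the test oracle is an independent brute-force step-up.
Clusters are 26-connected components of the significant mask, split by t
sign before labelling (so adjacent positive and negative effects never
merge), peak = max |t| with ties broken to the lowest linear index, extent
threshold `min_extent = 10` voxels by default (the analysis emulated here
reported no extent threshold but no cluster under ~70 voxels; 10 is a
conservative, configurable floor). World coordinates are `affine·(i,j,k,1)`
with 0-based indices; only world coordinates appear in tables.

**Dissociation report.** Regions are the FDR-significant gFCD clusters.
The gFCD sign is the cluster sign; the GMV sign is the sign of the mean GMV
*effect* over the cluster **core** — voxels at or above half the cluster's
peak |gFCD effect|. Two numerical facts force this choice: (i) in the
halo created by smoothing a strong effect, the *t* statistic stays high far
from the true locus, because the halo's noise is the kernel-scaled image of
the core's noise — t does not localize; the effect map decays like the
kernel and does. (ii) Averaging over the whole cluster lets global
between-subject variation (shared across all voxels) swamp a localized
structural effect. The report flags whether any cluster voxel survives the
GMV FDR threshold, and counts concordant/discordant regions.

Correlation tables report Pearson r per (ROI, pair): gFCD–GMV within each
group, and gFCD/GMV against JOA score and illness duration within patients,
with raw two-sided p and BH-adjusted p side by side across the whole table
family (both are shown because sub-threshold raw correlations that fail
correction are a common and reportable outcome). Zero-variance cells are
flagged undefined (NaN), never raised.

## Synthetic cohorts

The generator emulates the emulated study's design: two groups of 35, 180
volumes at TR 2 s on a 3 mm grid, ages from one shared normal
(mean 54, SD 6.7 — matching by construction), gender balanced 17/18 per
group, JOA scores (uniform integers 6–16) and illness duration (log-normal,
median ≈ 30 months) for patients only.

**Connectivity.** A community with loading c gives each member the series
`sqrt(c)·latent + sqrt(1−c)·private` (all standard normal, scaled by
`noise_sd`), so member pairs correlate at exactly c in expectation and the
expected gFCD of a member of an m-voxel community is m − 1 when c exceeds
the analysis threshold — recovery is testable against an analytic truth.
Background voxels are independent noise. Group effects on gFCD are planted
by **membership**, not amplitude (correlation is amplitude-invariant):
"increase" plants the community only in patients, "decrease" only in
controls; the planted community's correlation is its `loading` (default
0.7).

**Motion.** Slow sinusoids (≤0.15 mm / ≤0.12°) plus small jitter — well
inside the 2 mm / 2° exclusion limits — with spikes as persistent 0.8 mm
steps of alternating sign, placed after the discard window with ≥2-volume
spacing, so each spike raises FD above 0.5 mm at exactly one volume.

**GMV.** A shared smooth baseline field (level 0.6, spatial SD 0.1), a
per-subject global offset (SD 0.05 — the between-subject scale), i.i.d.
voxel noise (SD 0.02), patient-group regional shifts of
`d × between-subject SD`, clamped nonnegative and zero outside gray
matter. The global offset deliberately correlates voxels within subject,
as whole-brain volume variation does in real VBM data.

**Masks.** Gray matter is an ellipsoid inscribed in the grid (semi-axes
0.45 of each dimension) — a brain is a blob inside the bounding box — with
two small interior blocks carved out as white matter and CSF.
`default_cohort_spec` places two shared hub communities and three effect
regions (27-voxel cubes) well apart inside the ellipsoid; it assumes grids
of at least ~16 voxels per axis.

**Reproducibility.** Every array draws from a seed sequence keyed by
(master seed, stream, subject, group), so regeneration is bit-identical and
adding subjects never perturbs earlier subjects' data.

### What the synthetic validation does not show

The simulator has no hemodynamics, no spatial autocorrelation in the
background noise, no physiological (cardiac/respiratory) signal, no real
anatomy, and its effects are homogeneous cubes. Passing recovery tests
therefore demonstrates the *correctness of the computation* (counting,
filtering, regression, inference, reporting) under known truth — not that
the thresholds would behave identically on scanner data, where smoothness
and artifact structure differ. The headline case–control numbers of the
emulated study derive from 70 real subjects' scans that are not public and
are not reproducible here; validation is property-based by design.

## Problem sizes and defaults

Recovery experiments run at deliberately modest sizes chosen to exercise
every code path with comfortable statistical margins: oracle equivalence on
grids up to 8³ × ≤80 volumes; degree recovery with one 12-voxel community
(c = 0.7) on a 12³ grid over 20 seeds; null calibration with 10 vs 10
subjects × 10,000 independent voxels × 50 runs; dissociation recovery with
15 vs 15 subjects on a 20³ grid (≈4,200 gray-matter voxels) over 20 seeds.
Analysis defaults: `n_discard 10`, `fd_thresh 0.5 mm`, band `0.01–0.08 Hz`,
`R 0.6`, `FWHM 6 mm`, `alpha 0.05`, `min_extent 10`; all configurable via
`RunConfig` and logged in `run_log.yaml` on every pipeline run.

## Known limitations

- No slice-timing, realignment, normalization or segmentation: spatially
  raw data cannot be fed to this package.
- Only global FCD (degree); no local FCD or weighted variants.
- No permutation or cluster-mass inference; FDR is voxel-level only.
- Cluster tables carry coordinates, not anatomical labels.
- The ideal Fourier band-pass assumes an uninterrupted, uniformly sampled
  series; it is the reason spikes are regressed rather than deleted.
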