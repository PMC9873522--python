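# Methods

## The model of neurovascular coupling used here

Neurovascular coupling is operationalized at the map level: if local blood
supply tracks neuronal activity, then across gray-matter voxels a subject's
CBF map should correlate with a map of local activity/connectivity.  Two
indices are computed per subject:

- **Global coupling** `r_s = corr(CBF_z, DC_z)` over all usable gray-matter
  voxels, where both maps have been z-scored and smoothed (6 mm FWHM).
  Pearson correlation is invariant to the z-scoring; the smoothing is part
  of the per-subject map definition.  The group comparison tests these
  per-subject r values directly (no Fisher transform; the normality gate and
  the Mann–Whitney fallback make the test robust to the bounded scale, and
  the comparison is of identically-constructed quantities).  Groups smaller
  than four fall through to Mann–Whitney because the normality check is
  undefined there.
- **Regional coupling**, the CBF/DC ratio computed voxel-wise from the
  *original* (unsmoothed, un-z-scored) values, then z-scored over gray
  matter and smoothed.  Voxels whose DC falls below a small positive floor
  (`min_metric`, default 1e-6 on the normalized-DC scale) are excluded
  rather than epsilon-padded: a near-zero denominator would otherwise
  manufacture arbitrarily extreme ratios that dominate the z-scoring.

## Subject-level pipeline

Order: drop the first 10 volumes → one OLS per voxel removing intercept,
linear trend, white-matter and CSF mean signals and the Friston-24 motion
expansion (the global signal is additionally removed on the DC branch only)
→ band-pass 0.01–0.1 Hz (DC branch) → metric → z-score → 6-mm smoothing.

Choices worth stating:

- The band-pass is frequency-domain masking of the real FFT (a bin is kept
  iff its frequency lies in the band).  It is deterministic, exactly
  mean-removing, and has no order parameter.
- Linear detrending is implemented as intercept+trend columns inside the
  nuisance OLS, so residuals are exactly orthogonal to every regressor in
  one pass.
- The Friston-24 lag column backfills the first row with 0, the common
  toolbox convention.
- fALFF is the standard amplitude-ratio: in-band Fourier amplitude over
  total positive-frequency amplitude, computed on the detrended,
  nuisance-regressed (not band-passed) series; it lies in [0, 1].
- Degree centrality counts positive edges r ≥ threshold (default 0.2;
  0.15/0.25 as robustness settings) over in-mask voxel pairs and divides by
  M−1, yielding a degree fraction in [0, 1].  The verbal "number of edges"
  definition and typical reported magnitudes (~0.01) are reconciled by this
  normalization; a weighted (sum of supra-threshold r) mode is available.
  The correlation pass is blocked matrix multiplication on temporally
  standardized series; the block size is a memory knob verified to leave
  results identical to 1e-10.
- Gaussian smoothing is mask-renormalized: the map and the mask are both
  convolved and divided, so in-mask constants are preserved and no signal
  bleeds across the mask edge.  Missing voxels carry zero weight and stay
  missing.
- CBF maps are z-scored over the whole-brain mask (the perfusion-map
  convention); DC, fALFF and ratio maps over gray matter.
- z-scores use the sample SD (N−1); immaterial at realistic voxel counts
  but pinned down for small test fixtures.

## Group inference

The "two-sample t-test adjusting for covariates" is the GLM contrast: per
voxel, OLS of `value ~ intercept + group + age + sex + education`; the group
coefficient's t (df = n − rank) is the statistic map.  Analyzed voxels are
those in-mask and non-missing in *every* subject.  Voxels with zero residual
variance at the data's scale are set missing unless the group effect is
itself zero (identical maps), which reports t = 0.

**Smoothness** is estimated from normalized GLM residuals: residual vectors
are scaled to unit sum of squares per voxel; the mean squared forward
difference along each axis estimates 2(1−ρ(1)) of the underlying
unit-variance field, giving FWHM = sqrt(4·ln2 / λ) voxels per axis (floored
at half a voxel).  For white noise this evaluates to ≈1.18 voxels; smoothing
with a 6-mm kernel on a 3-mm grid yields ≈6.5–7.0 mm (the quadrature
combination with the intrinsic lattice roughness), which the tests verify.

**Cluster correction** follows Gaussian-random-field theory.  The
voxel-forming threshold is the two-tailed `voxel_p` quantile of t(df)
(default 0.005); positive and negative excursions are labelled separately
(26-connectivity by default).  The t threshold is Gaussianized by matching
tail probability, and the expected cluster count is the expected Euler
characteristic with the full resel vector — lattice counts R0..R3 of the
mask (Worsley-style point/edge/face/cube counts) times the Gaussian EC
densities.  The boundary terms matter for the small, curved masks this
package analyzes.  Cluster extent is modelled as
P(n ≥ k) = exp(−β k^(2/3)) with β = (Γ(5/2)·Em/EN)^(2/3), and the
familywise cluster p is 1 − exp(−Em·P(n ≥ k)).  For a two-tailed map both
the voxel p and the cluster p are split evenly across the signs, so the
overall familywise rate matches the nominal level.

Calibration: on stationary smooth Gaussian null fields with known 9-mm
smoothness (3 voxels) on a 24³ mask, the measured familywise rate is ≈0.03
against the nominal 0.05 — mildly conservative, as expected for the
lattice approximation.  Random-field cluster inference is unreliable below
about 3 voxels FWHM; the calibration suite therefore operates at 9 mm, and
the group analyses in practice sit near 8–9 mm estimated smoothness after
6-mm smoothing of structured maps.

Scalar statistics mirror mainstream clinical software: Lilliefors-corrected
KS normality (parameters estimated from the sample), pooled-variance
two-sided t-tests (raw or from summary moments), exact Mann–Whitney for
small untied samples (tie/continuity-corrected normal approximation
otherwise), Pearson chi-square *without* continuity correction for the 2×2
sex table, and Pearson correlations with the t-approximation p.

## The synthetic cohort generator

The generator emulates the data conditions of a pediatric two-group coupling
study: 26 patients vs 35 controls; 210 volumes at TR 2 s (10 dropped by the
analysis); a 24³ grid of 3-mm voxels holding a spherical brain phantom
(radius 8 voxels) partitioned into GM, a central WM sphere and a small CSF
sphere; ages ~N(11.8, 2.7²) truncated to 6–16 years, balanced sex, education
≈ age − 5; patient IQ centred at the emulated study's moments (PIQ 84 ±
16.8); motion traces are smooth random walks far inside the 2 mm / 2°
screening bound.

BOLD: K = 4 Gaussian network blobs (9-mm FWHM, shared across subjects) with
per-subject loadings ~N(1, 0.1²) and independent band-limited (0.01–0.1 Hz)
unit-variance time courses; voxel series are loading-weighted sums plus
white noise (SD 0.5 against unit blob peak).  Network voxels therefore
correlate strongly (high DC), background voxels weakly.  Noise is
temporally white by design — the analysis band-pass shapes it — so no AR
structure is modelled.

Decoupling injection: in patients, loadings inside a focal spherical region
(radius 2.5 voxels around a network centre) are attenuated by a per-subject
factor ~N(0.5, 0.15²) clipped to (0.15, 0.95).  Their DC drops there while
CBF does not follow, producing the regional ratio elevation.

CBF: `baseline (50) + b_g · z(expected-DC field) + smooth noise` (6-mm
smooth, SD 5 over GM).  The expected-DC field is computed in closed form
from the population correlation structure of the generative model, passing
population r through the Fisher-z sampling distribution at the band-limited
effective sample size so the threshold is smoothed the way empirical DC
smooths it.  The group gain b_g is calibrated so the *measured*
post-pipeline coupling hits the group target (0.35 controls, 0.25
patients): a deterministic internal pilot (fixed seed; three reference
subjects through the DC path plus reference noise fields) measures the
post-smoothing variances and covariances, and b solves
`target = b·az / sqrt((b²·v_z + v_eta)·v_d)`.  Infeasible targets (beyond
the noise-free ceiling) raise an error.  The calibration is verified
empirically by the acceptance suite.

Clinical injection: each patient's latent regional ratio is the closed-form
expected CBF/DC ratio in the decoupling region given their attenuation
factor; PIQ is drawn so its correlation with that latent is exactly the
target (−0.4) within each group, with VIQ/FIQ as correlated companions.
The latent is stored in the ground truth.  Measured recovery through the
full pipeline (cluster means vs PIQ) is attenuated by measurement noise and
is checked directionally; exact recovery is checked on the latent variable,
which the generator exposes through the same sampling path used inside
cohort generation.

What the generator does **not** emulate: hemodynamic response dynamics,
ASL noise physics, motion-corrupted images (motion affects only the trace
files), spatial inhomogeneity of real GM, registration error, multi-site
effects.  Passing tests therefore demonstrate the statistical machinery is
correct under the stated generative model, not robustness to real-data
artifacts.

## Problem sizes in the test and acceptance suites

All simulation-based checks are sized to run on one CPU in minutes, as the
package's own choice of test scale: cohort-level recovery uses the full
26-vs-35 groups on the default 24³ grid over 10 effect seeds and 6 matched
null seeds; the null-field calibration uses 500 fields; the clinical
recovery uses 200 resimulated patient groups through the generator's
clinical sampling path; determinism is verified bit-for-bit on an
8-vs-8 cohort.  The spherical phantom's GM holds ≈2100 voxels, so a full
cohort analysis (generation + subject pipelines + three GLM families with
cluster correction) completes in ≈10 s.

## Known limitations

- Resampling/registration is out of scope: all inputs must share one grid,
  and grid mismatches raise rather than resample.
- The GRF cluster p is mildly conservative (see calibration above) and, like
  all random-field methods, approximate below ~3 voxels of smoothness.
- The ratio index is undefined where DC ≈ 0; the floor rule excludes such
  voxels per subject, and the group stage analyzes only voxels usable in
  every subject.
- Global-signal regression on the DC branch is a convention switch
  (`global_signal_dc`); with it off, DC magnitudes and hence ratio scales
  change.
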