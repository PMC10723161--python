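# Methods

This note documents the models, parameter choices and numerical decisions
behind `seedfc`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Synthetic cohort generator

### Generative model

Each network (DMN, SN, CEN) carries a latent signal *s(t)*: Gaussian noise
band-limited to 0.01–0.08 Hz (resting-state fluctuations; band-limiting
guarantees non-degenerate power after the 0.01–0.1 Hz analysis band-pass),
standardized to unit SD. A *seed region* carries *s(t)* with unit coupling.
Every other region of the network follows

    y(t) = (a_g + b(t)) · s(t) + nuisance + ε(t)

- `a_g` — per-group static coupling (defaults NC 0.70, aMCI 0.55, AD 0.40:
  a plausible "disease lowers coupling" ladder producing clearly separated
  static FC at desk-scale group sizes).
- `b(t)` — zero-mean AR(1), stationary SD `τ_g` (defaults AD 0.35,
  aMCI 0.15, NC 0.25: group-distinct, deliberately non-monotone in disease
  severity, echoing reports that variability can go either way), with
  correlation time 40 s: slow enough to read as coupling dynamics, fast
  enough to decorrelate across 100 s windows.
- nuisance — (i) per-voxel linear drift, slope SD 0.5 per scan;
  (ii) motion artifact: per-voxel random loadings on the six standardized
  rigid-body parameters, total amplitude 0.2 (motion itself is a random
  walk, step SD 0.02 mm / 2·10⁻⁴ rad per volume, giving mean framewise
  displacements around 0.05–0.15 mm — typical for usable clinical scans);
  (iii) shared WM and CSF signals (amplitude 0.5 in their own compartment,
  30% leakage into gray matter) that the WM/CSF mean regressors are meant
  to remove.
- `ε(t)` — white-in-time Gaussian noise, SD 1.0, with **intrinsic spatial
  smoothness** of 2 voxels FWHM (6 mm at 3 mm voxels), emulating the
  point-spread of EPI acquisition plus interpolation. Spatially white noise
  is not a realistic null for cluster-level random-field inference and
  breaks its assumptions; see §4.

Geometry: a brain ellipsoid (semi-axes 0.45 × grid) containing a central
white-matter ball (radius 0.20 × min grid) around a CSF ball (0.10 × min);
gray matter is the remaining shell and serves as the analysis mask. Voxels
outside the brain are identically zero — they feed no downstream quantity
(the analysis mask and the nuisance means are tissue-masked) and skipping
them keeps Monte-Carlo calibration affordable. Default desk grid: 24³
voxels of 3 mm, 210 volumes at TR 2 s; the three-network demo grid is
36×42×36 so that all three published seed coordinates (and reflected
target regions) fit inside the brain. For a single-network scene the
affine is chosen so the planted seed region sits exactly at the network's
published MNI seed coordinate.

Participant tables draw age, education, MMSE, MoCA from per-group normal
distributions matching the study population (e.g. AD MMSE 18.7 ± 4.5;
MMSE/MoCA clipped to 0–30) and sex from the per-group male fractions. The
head-movement covariate is the *realized* mean framewise displacement of
the simulated motion trace (Power convention, rotations on a 50 mm
sphere) — the source study says only "head movement" without defining the
summary; mean FD is the field standard and a config switch is unnecessary
because the covariate column is user-replaceable in the table.

Determinism: every output is a pure function of (scene, participant table,
seed); per-subject streams are derived from the scene seed plus a CRC32 of
the subject id, so cohorts are reproducible subject by subject and
insensitive to iteration order. Scenes are treated as immutable after
construction (geometry is cached on the instance).

### What the generator does *not* emulate

No anatomy beyond the three-compartment ellipsoid, no hemodynamic response
function, no physiological (cardiac/respiratory) cycles, no multi-site or
scanner effects, no spatial misregistration (images are born aligned — the
spatially-normalizing preprocessing steps of real pipelines are out of
scope by design). A green Monte-Carlo test therefore establishes that the
*analysis chain* behaves correctly under its stated assumptions, not that
it is robust to the full messiness of clinical data.

## 2. Preprocessing

Fixed order: drop the first 10 volumes → one joint least-squares
regression of [intercept, linear trend, Friston-24 motion expansion,
WM mean, CSF mean] → 0.01–0.1 Hz band-pass. Detrending inside the joint
regression (rather than as a separate pass) avoids re-introducing trend
components; band-passing last avoids re-introducing nuisance spectra.
The Friston-24 lag rows are zero-filled at t = 0. Constant or duplicate
design columns are dropped automatically (an all-zero motion file must not
make the design singular); any remaining rank deficiency raises an error
naming the collinear columns.

The band-pass is an ideal frequency-domain filter with raised-cosine
transition bands of half-width 0.005 Hz centered on the printed cutoffs
(the cutoffs sit at −6 dB). This makes the spectral contract exactly
testable (pass-band tones preserved, 2×high tones attenuated ≥ 20 dB) and
is idempotent on the pass band. No scrubbing/censoring is performed.

## 3. Connectivity maps

- Seed spheres are measured by **diameter** as printed (6 mm diameter ⇒
  3 mm radius ⇒ 7 voxels on a 3 mm grid when centered on a voxel center),
  closed Euclidean ball over voxel centers. The seed series is the
  unweighted mean over seed voxels.
- Fisher z with r clipped to ±(1 − 10⁻⁷); zero-variance voxels get z = 0
  and are flagged.
- Sliding windows are rectangular, length 50 TR, step 2 TR (validation:
  60 TR), trailing partial windows discarded: 200 retained volumes give
  exactly 76 (or 71) windows. Windowed correlations are computed by
  cumulative sums (exactly equal to the per-window loop, tested to 1e−8).
- **CV definition.** The windowed-z mean can approach zero, making
  SD/mean unstable. Default: CV = SD/|mean| where |mean| ≥ 0.05; below
  that the voxel receives the SD value and is flagged. A `variability_kind
  = "sd"` switch selects the plain SD everywhere. Note that the
  mean-normalized CV *inherits static coupling differences through its
  denominator*: groups differing only in `a_g` differ in mean z and hence
  in CV even with identical τ. Specificity of the variability readout to
  variability effects therefore holds for the SD variant only. The CV
  variant also has a hard power ceiling in group comparisons at desk
  scale: a 50 TR / 2 TR scheme on 200 volumes contains only ~4
  statistically independent windows, each subject's realized coupling
  trajectory is itself a ~10-degree-of-freedom sample of τ, and the
  denominator adds further noise — so the identifiability tests read
  variability effects from the SD variant. The |mean| (rather than
  signed-mean) convention keeps the CV map non-negative.
- Smoothing: 6 mm FWHM Gaussian (σ = FWHM/2.3548 per axis in voxel
  units), kernel-renormalized at the analysis-mask boundary so values are
  never mixed across the mask edge, then recentered to preserve the mask
  mean exactly (edge renormalization alone does not). Static z-maps are
  smoothed too (config-on by default): group inference needs comparable
  smoothness across map types; the source description is explicit only for
  the dynamic maps.

## 4. Group statistics and cluster inference

Voxelwise ANCOVA: partial F (2 numerator df) for the group factor
adjusting for age, sex (0/1), education and mean FD; covariates
mean-centered (the group F is invariant to centering and to affine
rescaling of covariates — property-tested). Implemented via QR projections
of the full and reduced models; residuals are standardized per voxel for
smoothness estimation. A residualize-then-ANOVA alternative is available
by passing `covariates=()` and pre-residualized maps.

Smoothness: per-axis λᵢ estimated as the mean squared forward difference
of the voxelwise-standardized residuals between in-mask neighbors;
FWHMᵢ = √(4 ln 2 / λᵢ); resels = V / ∏ FWHMᵢ. The estimator has a known
mild upward FWHM bias at coarse smoothness (2(1 − e^(−λ/2)) < λ), within
the tested 15% recovery tolerance.

Cluster correction: the F map is Gaussianized voxelwise
(Z = Φ⁻¹(1 − p_F)); components above u = Φ⁻¹(0.999) = 3.0902
(26-connectivity; 6/18 available) receive the classic extent-distribution
corrected p

    P(n ≥ k) = exp(−β k^{2/3}),  β = (Γ(5/2) · E[m] / E[N])^{2/3},
    p_cluster = 1 − exp(−E[m] · P(n ≥ k)),

with E[N] = V · voxel_p and E[m] = resels · ρ₃^F(f_u), the **unified-theory
3D EC density of an F field** at the equivalent F threshold. The
Gaussianized-F field is rougher than the Gaussian component fields whose
FWHM the residuals estimate; with the Gaussian EC density the expected
component count is roughly halved and the expected cluster extent doubled
at these df, which makes cluster p-values markedly conservative (the
empirical family-wise error of the corrected pipeline sat at the very edge
of its calibration band). The F-density reproduces both the observed
component count and the observed mean extent on simulated null cohorts;
the calibration test (100 null cohorts) asserts the resulting FWER band.
A 500-permutation max-cluster-size test provides a model-free cross-check
and agrees with the GRF decision on planted-effect replicates.

Post hoc: Welch two-sample t-tests on cluster-mean values for the three
group pairs, Bonferroni ×3, significance tiers at 0.05 and 0.01. Cluster
means (not voxelwise post hoc) because group bar plots per cluster are the
reporting convention.

## 5. Demographics and cognition statistics

`anova_from_summary` reconstructs the one-way ANOVA exactly from per-group
(n, mean, SD) — between-group SS from means, within-group SS = Σ(nᵢ−1)sᵢ² —
and is property-tested to agree with raw-data ANOVA to 1e−10. The sex table
uses Pearson chi-square without continuity correction (df = 2).
FC–cognition association uses partial correlation (residualize both
variables on intercept + head movement, age, sex, education; t with
df = n − k − 2), run in the pooled AD+aMCI subset only — controls are
excluded, matching the study design. The Bonferroni family for these
correlations is (number of significant clusters) × (number of scores);
the family is not defined in the source description, so it is recorded in
the report output.

## 6. Numerical and engineering choices

- Heavy Monte-Carlo paths store BOLD as float32 (regression/FFT in
  float32, correlation accumulations and GLM algebra in float64); oracle
  tests run in float64. Residual orthogonality holds to ~1e−6 (float64)
  per the regression contract.
- Preprocessing accepts a mask restricting per-voxel work to the brain.
- Degenerate inputs: empty seed masks, constant seed series, < 2 windows,
  rank-deficient designs, groups with < 2 subjects, zero-margin
  contingency tables and out-of-range p-values all raise `ValueError`
  with specific messages.
- Reports serialize floats at 3 decimals (cluster tables) / 6 significant
  digits (test tables); identical config + seed reproduces reports byte
  for byte, and every run writes a provenance JSON (config hash, seed,
  versions).

## 7. Known limitations

- The GM "anatomy" is a spherical shell; anatomical labels for cluster
  tables require a user-supplied atlas label map (none is shipped).
- Cluster-extent theory is applied at desk-scale smoothness (total field
  FWHM ≈ 2.8–3.2 voxels); its tail approximation is only moderately
  accurate there, which is exactly why the calibration and permutation
  cross-check tests exist.
- The CV statistic is intrinsically confounded with static coupling
  strength (§3); interpret CV group differences accordingly or use the SD
  variant.
- One-sample T "network pattern" maps are supported only as ordinary maps
  through the same machinery; no reference patterns are reproduced.
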