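# Methods

## The analysis this package implements

The pipeline reproduces an ROI-based representational similarity analysis
(RSA) of a modified Go/NoGo ("intentional inhibition") task, comparing a
Tourette-syndrome (TS) group against a comparison (CN) group. On each trial
a cue instructs a button press (Go), instructs withholding (NoGo), or lets
the participant choose (Choose). The analysis path is:

1. **First-level GLM.** Each analysed outcome condition (Go, NoGo-correct,
   Choose-Go, Choose-NoGo, plus Go-omission and NoGo-error nuisance
   conditions when present) is modelled as a 0.5 s boxcar at the cue
   onsets, convolved with the canonical double-gamma HRF. The three runs
   are concatenated with one constant column per run, a run-transition
   regressor on the first volume of runs 2 and 3, six motion-parameter
   regressors, and — for TS participants — a tic regressor built from
   observed tic onsets/durations. Single-regressor t-maps are formed for
   the four analysed conditions against the implicit inter-trial baseline.
2. **ROI patterns.** Six 10 mm spheres at fixed MNI peaks (preSMA 4/18/48,
   IFG 40/40/6, right insula 34/22/4, left insula −34/20/4, caudate
   −12/18/−2, M1 −34/−22/56) are rasterised onto the analysis grid; a
   voxel belongs to a sphere when its centre is within the radius
   (boundary inclusive). On a 3 mm grid a centred 10 mm sphere contains
   exactly 171 voxels.
3. **Similarity.** Within each ROI, the four t-map patterns are correlated
   pairwise across voxels (Pearson), Fisher transformed
   (z = atanh r, |r| clipped at 1 − 1e−7), and each of the four
   pre-registered contrasts (Go–NoGo, ChooseGo–ChooseNoGo, Go–ChooseGo,
   NoGo–ChooseNoGo) reads out one unit-weighted cell of the 4 × 4 matrix.
4. **Inference.** Per ROI and contrast, group differences are tested with
   two-tailed Student (pooled-variance) t-tests, reported with the default
   two-sample JZS Bayes factor (Cauchy prior on effect size, scale 0.707).
   p-values are BH-FDR adjusted within the six-ROI family of each
   contrast. Symptom associations (YGTSS severity, PUTS) use two-tailed
   Pearson tests with the default stretched-beta correlation Bayes factor
   (width 1 = uniform prior on ρ), FDR-adjusted the same way. The joint
   decision rule rejects when p < 0.05 **and** BF10 > 3.

The group t statistic is computed as CN − TS, so greater similarity in the
TS group yields negative t, matching the sign convention of the reported
tables.

## Bayes-factor computation

Both Bayes factors are computed by adaptive quadrature (absolute tolerance
1e−10, guaranteed ≤ 1e−6) rather than closed forms:

- **Two-sample JZS.** BF10 = ∫ T_ν(t; δ√n_eff) Cauchy(δ; 0, 0.707) dδ /
  T_ν(t; 0) with ν = n1 + n2 − 2 and n_eff = n1·n2/(n1 + n2), where
  T_ν(·; μ) is the noncentral-t density.
- **Correlation.** BF10 averages the exact sampling density of Pearson r
  (hypergeometric form, evaluated in log space) over the stretched beta
  prior on ρ, against the ρ = 0 null.

Unit tests cross-check both against an independent implementation
(pingouin) and against the published values; monotonicity in |t| and |r|,
sign symmetry and the reciprocal identity are property-tested.

## Synthetic cohorts: what is emulated

The generator reproduces the study's design constants: 3 runs × 288 trials
(432 Go / 144 NoGo / 288 Choose per session, split equally across runs),
800 ms cues, ITIs drawn from {1000, 1130, 1250, 1380, 1500} ms at
35/30/20/10/5 % (largest-remainder apportionment, so the counts are exact,
then shuffled), TR 2.52 s and 250 analysed volumes per run (5 optional
steady-state dummies). Behavioural outcome rates default to the group
means (%Choose-Go 53 % CN / 56 % TS, NoGo errors 3 %, Go omissions
1 %/2 %), with truncated-normal RTs around the reported means.

The **representational geometry is planted** per subject: a 4 × 4 target
correlation matrix is realised in expectation by mixing i.i.d. Gaussian
voxel components through the symmetric square root of the target
(`P = R^{1/2} G`), the general form of the shared/unique decomposition
√ρ·g + √(1−ρ)·u. Group-mean Fisher-z targets default to the preSMA group
means of the emulated study (CN 1.596/1.461/1.402/1.209, TS
1.853/1.715/1.714/1.510 for the four pre-registered pairs; the two
unreported pairs are filled with the mean of the four). Between-subject
variation is a common Gaussian shift of all pairs on the z scale
(SD 0.3, consistent with the reported group-difference t values at the
reported means).

Voxel time series are the planted pattern times an HRF-convolved event
regressor (amplitude 6 in units of the white-noise SD 1), plus a 3-term
low-frequency cosine drift, a component correlated with random-walk motion
parameters, tic-locked HRF responses in TS subjects (homogeneous Poisson
tic process; subject rates gamma-mixed so session tic counts are
negative-binomial with mean ≈ 161 and SD ≈ 147), and white noise. Outside
the ROI only drift and noise are present. The signal-to-noise default is
chosen so that the t-map correlation estimator is effectively unbiased
(attenuation from estimation noise < 2 % on the Fisher-z scale at the
test scale) — matching the near-ceiling pattern correlations (r ≈ 0.85 to
0.96) on which the analysis operates.

Symptom scores are Gaussian linear mixtures of the subject's standardised
similarity shift and independent noise (YGTSS severity ~ N(26, 9²) clipped
to 0–50; PUTS ~ N(23, 7²) clipped to 9–36), giving a controllable
population correlation with similarity; the default target correlation is
0 (the reported symptom correlations did not survive FDR correction, so
no coupling is assumed by default). Medication status is Bernoulli(9/23)
in the TS group.

### What the simulator does not emulate

No k-space physics, slice-timing, susceptibility distortion, spatial
autocorrelation/smoothness, physiological noise spectra, or anatomical
structure: passing recovery tests show the estimator chain is correct
under the stated generative model, not that the pipeline is robust to all
properties of real scanner data. Temporal autocorrelation of the noise is
white by design (see below).

## Numerical and design choices

- **Estimator.** Plain OLS, no AR(1) pre-whitening and no default
  high-pass filter (both available as switches: `high_pass_cutoff`
  argument of the design builder). This keeps the estimator exact and
  testable; the RSA consumes spatial t-patterns, which are insensitive to
  these temporal choices. Degrees of freedom are volumes − rank(design);
  rank-deficient designs are fitted with the pseudo-inverse and a warning.
- **Convolution.** Event boxcars are built on a 0.1 s microtime grid and
  sampled at frame midpoints ((i + 0.5)·TR); 0.5 s events are sub-TR and
  would alias on a TR grid.
- **Pseudo-randomisation.** Uniform shuffle with identical-cue run lengths
  capped at 6 by deterministic swap repair (the original constraint is not
  recoverable; an uncapped shuffle of 50 % Go trials would almost surely
  produce longer runs).
- **Sphere rasterisation.** Distance measured from sphere centre to voxel
  centres, boundary inclusive; no partial-volume weighting.
- **Zero-residual voxels.** Residual sums of squares at float-residue
  level (≤ 1e−20 of the signal energy) are clamped to zero so perfectly
  fitted voxels report t = 0 rather than 0/0 noise.
- **Fisher clipping.** |r| is clipped at 1 − 1e−7 before atanh (z ≈ 8.4);
  clip events are logged. Realistic values (z < 2.5) are unaffected.
- **Mean raw correlation.** Group tables report the mean of subject-level
  r alongside mean z (not tanh of the mean z); both columns are emitted.
- **Subject PSD guard.** After the per-subject z shift, the implied
  correlation matrix is eigenvalue-clipped back to PSD if the shift pushed
  it out (essentially never at default settings).

## Scaled test conditions

The full-scale session (864 trials, 750 analysed volumes, 40 × 48 × 38
grid) runs through the same code paths, but the test and validation suite
uses scaled designs on a 9³ grid holding one full 171-voxel ROI sphere:
planted-recovery uses 50 subjects at 72 trials/run × 72 volumes; the null
calibration uses 200 cohorts of 8 + 8 subjects at 36 trials/run × 40
volumes. These sizes were chosen as the smallest at which the binomial and
Monte-Carlo tolerances of the checks are meaningful.

## Known limitations

- The exact voxel sets of the original re-sliced masks are not
  recoverable; sphere rasterisation is nearest-neighbour on the analysis
  grid.
- BH idempotence does not hold for adjusted p-values (a property of the
  procedure itself, not of this implementation); the implementation is
  verified against the literal min-over-tail definition instead.
- The per-run condition composition (equal split of session totals) and
  the pseudo-randomisation cap are package choices where the original
  design is under-specified.
- With default (null) symptom coupling, symptom-correlation analyses
  exercise the machinery but plant no effect to recover; set
  ``r_ygtss``/``r_puts`` to test recovery.
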