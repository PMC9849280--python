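# Methods

This note documents the models and procedures implemented in `ppgbp`, the
assumptions behind them, the tunable parameters that matter, and what the
synthetic world does and does not establish.

## The estimation problem

During a phenylephrine pressor challenge, arterial and venous
vasoconstriction raise blood pressure by tens of mmHg over ~20 minutes
while the baroreflex slows the heart. Arterial stiffening changes the
timing and amplitude of the reflected pressure waves that shape each PPG
pulse. The package estimates the *change* in blood pressure from baseline
(ΔSBP, ΔMAP, ΔDBP) from per-window summaries of PPG/ECG waveform features
under a **hybrid calibration** scheme: one baseline measurement per
participant plus demographics personalise a model trained on the rest of
the cohort.

## Synthetic cohort

Real pressor-study recordings are not redistributable, so every stage is
exercised on a generated cohort whose *statistical* structure matches the
study design. The generator is a stated world, not a biophysical
simulator (no Windkessel or pharmacokinetic modelling).

- **Protocol**: 5-min rest, 10-min dose ramp (0.2 mcg/kg/min steps each
  minute, 10 increments), 6-min maximum infusion, 8-min washout. All
  durations configurable.
- **BP response**: each participant's peak ΔSBP is drawn from a normal
  distribution with median 20 mmHg and IQR 8 mmHg, truncated at 30 mmHg;
  a configurable fraction (default 4/26) are strong responders drawn
  uniformly in 33–40 mmHg. The response follows the infusion rate through
  a first-order lag (60 s) and decays in washout (τ = 150 s). Peak ΔMAP
  and ΔDBP are fixed ratios (0.85, 0.775) of peak ΔSBP, matching the
  relative magnitudes of the three channels.
- **Reflex bradycardia**: hr = hr₀ − k·ΔSBP with k = 0.3 bpm/mmHg. The
  direction is physiological; the gain is a package choice (the source
  protocol states only the direction).
- **Stiffness → morphology**: a latent stiffness = clip(ΔSBP/40 mmHg, 0, 1)
  linearly interpolates each beat's 4-Gaussian parameters between a
  hand-tuned "rest" set (dominant systolic wave, clear notch) and a
  "maximum infusion" set (tall, early tidal wave, filled-in notch). This
  reproduces the qualitative morphology progression and — because ΔSBP is
  linear in stiffness and the pulse parameters are linear in stiffness —
  doubles as the known linear feature→ΔBP link used by the
  parameter-recovery tests.
- **Measurement layer**: cuff readings once a minute with Bernoulli
  dropout (p = 0.1) and Gaussian noise (SD 4 mmHg, inside the quoted
  ±5 mmHg bias / 8 mmHg SD device specification); PPG white noise,
  respiratory amplitude modulation, and flagged motion-artefact bursts;
  ECG P-QRS-T templates with baseline wander, optional 50 Hz interference
  and white noise. Sampling rates default to 125 Hz (PPG) and 256 Hz
  (ECG).
- **Ground truth** (beat onsets, per-beat pulse parameters, R-peak times,
  artefact intervals, the latent hemodynamics) is always emitted so
  detectors and fitters are tested against a known answer.

What a green test on this world establishes: the *algorithms* behave as
specified (detection accuracy, fit convergence, calibration arithmetic,
no leakage, recovery of injected links). What it does not establish:
clinical performance on real waveforms — real PPG has baseline drift,
probe-contact changes, arrhythmias and artefact structure the generator
does not model, and real feature→BP relationships are participant-specific
in ways a single latent stiffness cannot capture.

## Preprocessing

- PPG: 8th-order Butterworth band-pass 0.5–10 Hz, applied
  forward–backward (zero phase preserves fiducial timing; phase handling
  is a package choice). Pulse feet are found by maximum-upslope detection
  followed by a local-minimum search; beats are delimited foot-to-foot,
  resampled to 100 points (cubic spline), min–max normalised, and
  differentiated with a 7th-order Savitzky–Golay filter (window 11 — the
  window length is a package default; only the order is prescribed).
- Beat quality (SQI): Pearson correlation against a running template
  (mean of the last 20 accepted beats), clipped to [0, 1]; the first beat
  of a record scores 1. Threshold 0.8 everywhere.
- ECG: 8th-order Butterworth high-pass 0.5 Hz plus a 2nd-order notch at
  the mains frequency, zero phase. QRS detection is Pan–Tompkins
  (band-pass, derivative, squaring, 150-ms integration, adaptive
  signal/noise thresholds, refractory 250 ms). Block-wise ECG quality is
  the agreement fraction (±50 ms) between Pan–Tompkins and an independent
  amplitude-threshold detector, multiplied by an R-R regularity factor
  (fraction of intervals within 15% of the block median and inside
  0.3–2.0 s). The regularity factor is needed because two detectors fed
  the same broadband noise agree by construction; agreement alone does
  not discriminate noise from rhythm.
- PAT = pulse-foot time − nearest preceding R-peak time; values outside
  0.05–0.8 s are kept but flagged with zero quality. The foot (onset)
  fiducial is a config choice.

## 4-Gaussian pulse decomposition

Each normalised beat is modelled as ζ(t) = Σᵢ₌₁⁴ A_i exp(−(t−μ_i)²/2σ_i²):
incident systolic wave, tidal wave, dicrotic wave, residual re-reflections;
g_s = g₁+g₂ and g_d = g₃+g₄ are the systolic/diastolic components. The RMSE
loss is minimised by bounded least squares (scipy trust-region reflective —
the bounded stand-in for Levenberg–Marquardt) with analytic Jacobian.
Constraints: all parameters ≥ 0, amplitudes ≤ 1, and monotone means
enforced smoothly by the reparameterisation μ_i = μ_{i−1} + δ_i, δ_i ≥ 0.
σ is floored at 10⁻⁴ to avoid singular components. Tolerances 10⁻⁸, at
most 400 function evaluations per beat.

Seeding: the first beat starts from the canonical evenly-spread set
(A = 0.9, 2/3, 0.5, 1/3; μ = 0.2, 0.4, 0.6, 0.8; σ = 0.1). The printed
seed width of 0.01 is interpreted as a *variance* (σ = 0.1): the model
formula uses σ as a standard deviation, and 0.01 as a standard deviation
would start from needle-thin spikes rather than "evenly distributed
Gaussians of equal width". Subsequent beats are seeded from the previous
converged fit, which keeps parameters continuous through the morphology
ramp. A fit RMSE above 0.03 zeroes the beat's quality index.

The problem is non-convex and not identifiable when components coincide:
a single isolated Gaussian may be represented as two coincident
half-amplitude components with identical loss. Tests therefore assert
reconstruction and bound contracts, not uniqueness, in the degenerate
case.

## Feature library

61 PPG features in five families (morphology 19, VPG 4, APG 8, Gaussian
21, PCA 9), 10 ECG features, 6 static columns (age, sex, height, weight,
BMI, BP calibration value) — 77 in total. Conventions worth noting:

- Times are normalised beat fractions; systole/diastole split at the
  dicrotic notch. The systolic peak is the *first* turning point above
  the pulse midpoint (prominence ≥ 0.01 guards numerical ripple), which
  stays correct when the tidal wave grows taller than the systolic peak.
  When the notch is lost the fallback is the most prominent APG maximum
  after S, flagged "inferred".
- NHA uses the first 10 harmonics of the beat's own fundamental
  (1/duration); the harmonic count is a package default.
- The Gaussian reflection index is computed exactly as printed in its
  source (area(g_s) − area(g₃)) even though area(g_d) may have been
  intended; areas are trapezoidal quadratures on the unit interval. The
  LVET approximation is the time where g_s falls below 1% of its maximum
  after its peak (the cited definition is not restated in the source;
  the approximation is isolated in one function).
- Missing fiducials propagate NaN — never silent zeros.
- The PCA basis pools good-quality beats (SQI > 0.8) across the cohort,
  resampled to 100 points and mean-normalised; eigenvectors come from the
  SVD of the centred matrix with a fixed sign convention
  (largest-magnitude loading positive). The pipeline pools across all
  participants; a leakage-safe per-fold basis can be fitted by calling
  `fit_pca_basis` on training-fold beats.
- ECG features are computed on the filtered waveform per analysis window:
  Hjorth mobility/complexity, Higuchi fractal dimension (k_max = 17),
  Shannon entropy (16 amplitude bins), approximate entropy (with
  self-matches), sample entropy (without), and multiscale sample entropy
  at scales 2, 4, 6, 8 with m = 2 and r = 0.2·SD of the window. Windows
  are decimated (default ×4 → 64 Hz) before the O(n²) entropy
  computations to bound runtime; Hjorth/fractal/Shannon use the full
  rate.

## BP reference

Each cuff channel is smoothed with a natural cubic smoothing spline
minimising p·Σ(yᵢ−f̂(tᵢ))² + ∫f̂″(t)²dt. The solver is scipy's
`make_smoothing_spline` with λ = 1/p — the identical objective up to the
positive factor p. Limits: p→∞ interpolates the readings; p→0 collapses
to the linear least-squares line (the penalty's null space is the linear
polynomials — not cubics, which have nonzero roughness). One common p per
channel is chosen by leave-one-out RMSE on a log grid 10⁻³…10⁸ (12
points, one per decade), averaged participant-wise; participants with
fewer than four readings are excluded from a candidate's average.

## Dataset assembly

Features are averaged over 40-s windows centred on each reference BP
sample using only good-quality beats; a window where more than half the
beats are bad (or that is empty) is missing. ECG windows are gated
analogously on block quality. Streams are then conditioned per
participant: ±5 MAD outliers against a 10-row rolling median are removed,
a scalar random-walk Kalman filter (process/measurement variances
apportioned 20/80 from the first-difference variance; constant streams
pass through unchanged) smooths transients, and remaining gaps are filled
by nearest-neighbour imputation in time.

Calibration divides each feature by its rest-period mean
(x = (f−f̂)/f̂) and subtracts the rest-period mean reference BP from the
targets; a participant with no rest-period rows is calibrated on a
one-minute window centred on their first cuff inflation. Demographics
plus the BP calibration value join as static columns (treated as
continuous). Augmentation adds rows on a 1/15 Hz grid (15-s windows so
windows stay disjoint); training and validation use the augmented set,
evaluation always the original grid.

Collinear features are removed iteratively: the feature with the largest
VIF = 1/(1−R²) is dropped until all VIF ≤ 10 (equivalently R = 0.9480…,
anchored by VIF(R² = 0.9) = 10 exactly). Demographics are exempt so they
survive to the importance analysis. Condition numbers are reported on the
standardised design (features carry arbitrary units, so κ of the raw
matrix would be scale-dependent).

## Estimation

`DeltaBPModel(dataset, model_kind, channel, feature_set).fit(seed)` runs
nested leave-one-subject-out cross-validation: the outer loop holds out
one participant entirely; the inner loop (LOSOCV over the remaining
participants) selects the hyperparameter minimising mean inner RMSE,
scored on unaugmented rows to mirror the outer evaluation; the fold model
retrains on all inner augmented rows and is evaluated on the held-out
participant's unaugmented rows. Metrics per fold: Pearson ρ_p (missing
when fewer than 3 rows or a constant side), RMSE, MAE.

- **LASSO+OLS**: features standardised with training-fold statistics;
  the L1 path selects a support, then OLS refits on it (coefficients
  reported on the original scale). λ grid: 30 log-spaced values spanning
  [λ_max·10⁻⁴, λ_max] with λ_max = 2·max|Zᵀ(y−ȳ)| (data-driven; the grid
  shape is a package choice). λ = 0 is exact OLS; an empty support
  degrades to an intercept-only model.
- **Random forest**: 300 bootstrap trees, squared-error splits, tuned
  per-node feature count mtry over {⌈M/10⌉, ⌈M/3⌉, ⌈M/2⌉, M};
  deterministic given the seed (one master seed fans out per fold).
- **Baseline reference**: ΔBP ≡ 0; its correlation is reported missing,
  never zero.
- **Comparisons**: two-tailed Wilcoxon signed-rank on participant-paired
  fold metrics (exact null for n ≤ 25, normal approximation above),
  Benjamini–Hochberg adjustment across the family of comparisons.

## SHAP importance and ranking

Shapley attributions use the interventional value function
v(S) = E_z[f(x_S, z_{∖S})] over a background sample of training rows
(default 100, seeded).

- **Kernel SHAP** (linear models): kernel-weighted coalition regression;
  coalitions are enumerated exhaustively when 2^M−2 fits the sample
  budget and sampled from the Shapley kernel otherwise. For a linear
  model the coalition value has a closed form over the background mean,
  which makes the regression exact at any dimensionality; the analytic
  identity φ_j = β_j(x_j − z̄_j) serves as an independent oracle in tests.
- **Tree SHAP** (forests): an exact per-(tree, background-sample) path
  algorithm — a single traversal tracks the features on which foreground
  and background diverge; each leaf contributes with weight
  a!b!/(a+b+1)! to the diverging features. Averaging over trees and
  background uses Shapley linearity. Verified against exhaustive
  enumeration of the 2^M coalitions for small M.
- Local accuracy (φ₀ + Σφ_j = prediction) is asserted for every explained
  row in both engines.

Per fold, a feature's importance is its mean |φ| across (a subsample of)
the training rows; features are ranked per fold (average ranks on ties)
and rescaled to (M − rank)/(M − 1) ∈ [0, 1]. Medians and ranges across
folds summarise stability, and Kendall τ-b on median coefficients
quantifies agreement between BP channels.

## Numerical choices and degenerate inputs

- Filters reject configurations that would be unrealizable
  (fs ≤ 2·cut-off); flat signals yield empty beat lists / empty QRS
  annotations with zero quality rather than errors.
- The spline p→0 limit is verified to ~10⁻³ mmHg rather than machine
  precision: the solver's conditioning at λ = 10¹⁴ on second-scale time
  grids sets a double-precision floor near 3·10⁻⁵.
- Zero rest-period feature means abort calibration for that feature
  (division guard) with a warning; wholly-missing features are dropped
  per participant.
- Perfectly collinear columns produce infinite VIF and are removed first.

## Known limitations

- The synthetic APG ensemble is noisier than real averaged beats: the
  Savitzky–Golay second derivative amplifies residual in-band generator
  noise, so only ~60% of APG-ensemble variance falls in the top three
  principal components (PPG ≈ 98%, VPG ≈ 90%). This is a property of the
  additive-white-noise model, not of the PCA step.
- Gaussian decomposition parameters are not identifiable when components
  coincide; downstream features built from sums/areas are stable, the raw
  per-component parameters less so on degenerate beats.
- Tree SHAP cost grows with trees × background × explained rows; the
  pipeline defaults subsample both (configurable) — exactness per pair is
  preserved, only the Monte-Carlo averaging over background/rows is
  reduced.
- Entropy features are computed on decimated windows (64 Hz default);
  absolute entropy values depend on that rate, so it is fixed in config
  and identical across participants.
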