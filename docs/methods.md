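# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `alphalat`, in the spirit of the
methods documentation of established simulation/statistics packages.

## Laterality indices

All indices are normalized right-minus-left differences, which cancel
subject-level scale factors (head size, overall oscillatory power, overall
performance):

* **LV_s** = (V_right − V_left)/(V_right + V_left) per subcortical structure,
  from a long-format voxel-count table; bounded by (−1, 1), positive =
  rightward asymmetry.  Nonpositive or missing hemisphere entries are errors,
  never silently imputed.
* **MI(α)_k** = (P_att-right − P_att-left)/(P_att-right + P_att-left) per
  combined sensor, where each power is first averaged over that cue side's
  trials, the 8–13 Hz band (six 1-Hz bins, closed interval) and the
  −850–0 ms pre-target window (closed interval).  Averaging order matters
  and is fixed: trials/band/window first, then the ratio.
* **HLM(α)** = mean MI over the right-ROI sensors + mean MI over the
  left-ROI sensors, bounded by (−2, 2); negative values mean the left
  hemisphere's alpha power is the more strongly modulated.  The ROI is the
  set of 5 mirror-symmetric sensor pairs with the largest group-level
  (unweighted mean over subjects) right-minus-left MI difference; ties at
  the cutoff break by ascending pair id.  The ROI is selected once from the
  all-trials group map and reused for condition-wise HLM(α); selecting
  per-condition ROIs instead would confound sensor choice with condition
  effects (the shared-ROI choice is deliberate and the per-condition
  recomputation only re-averages power within the fixed sensors).
* **BA** = (right − left)/(right + left) for per-side accuracy and mean RT.
  RT is summarized over correct trials only by default (configurable);
  "attended side" means cue side, regardless of response.

## Spectral estimation

Power is estimated with a frequency-dependent sliding window of 3 cycles
(300 ms at 10 Hz), stepped every 10 ms over the 2–30 Hz grid in 1-Hz steps:
each segment is demeaned, Hanning-tapered, zero-padded to the next power of
two, Fourier-transformed, and the squared magnitude at the padded-FFT bin
nearest the target frequency is recorded at the window center, scaled by
the taper gain 2/Σtaper so a unit-amplitude sinusoid reads near one
regardless of window length.  Centers where the full window does not fit
inside the epoch are NaN (no partial windows, avoiding edge bias in the
pre-target analysis interval).  Power at the two planar gradiometer
channels of a location is summed.  No baseline normalization is applied
anywhere: the downstream indices are self-normalizing power ratios, and a
per-frequency constant scale cancels in every MI.

Per-window demeaning stands in for the 1-Hz high-pass of a full
preprocessing chain (it removes DC and attenuates drift within each
window).  Computationally, the per-bin estimate is evaluated as a
correlation of the signal with the tapered complex exponential via FFT
convolution — one forward FFT of the data shared across frequencies and
kernels — which is algebraically identical to the per-window definition;
the test suite verifies agreement with a direct single-window oracle to
1e-10 relative error.

## Linear modelling

* **Exhaustive search.** All 2⁷−1 = 127 non-empty subsets of the seven LV
  regressors are fitted by OLS with an intercept and ranked by AIC (BIC
  always reported alongside).  Criteria use the Gaussian log-likelihood with
  constants retained, counting the intercept and the residual variance:
  AIC = −2logLik + 2(k+2).  The constant offset is ranking-invariant.
  With one observation per subject, random subject effects are not
  identifiable, so the model is fixed-effects OLS.
* **Inference.** Standard errors from the QR factorization; two-sided t
  tests on n−k−1 df; overall F against the intercept-only model with dfs
  (k, n−k−1); R², adjusted R², VIF_j = 1/(1−R²_j) from auxiliary
  regressions with intercept.  No multiple-testing correction is applied
  across the 127 search models; the search reports raw criteria.
* **Multivariate multiple regression.** The four condition-wise HLM(α)
  values are four outcome variables sharing one design (not a summed
  outcome — per-condition coefficients require it).  The coefficient matrix
  equals column-wise univariate OLS; the residual covariance uses n−k−1 df.
  A regressor's effect across all outcomes is tested by Hotelling
  T² = b'S⁻¹b/c_jj, converted to F with dfs (p, n−k−1−p+1) — (4, 26) at
  n = 33, k = 3 — equivalent to Pillai/Wilks for a single-row hypothesis.
  Nested models compare via Wilks' Λ = det(E_full)/det(E_reduced) with
  Rao's F approximation (exact when min(p, hypothesis df) ≤ 2; the
  implementation reports its own dfs, and does not attempt to match any
  specific software's df convention for this comparison).
* **Distributional checks.** Shapiro–Wilk for normality (scipy's
  implementation of the standard approximation), one-sample two-sided t
  tests for LV lateralization against zero.

## The synthetic cohort generator

The generator emulates a cued change-detection study: 33 subjects, 4
load/salience conditions × 128 trials (512 total, matching 2 blocks of 256),
cue sides exactly balanced within condition.

* **Volumes.** LV_s ~ Normal(mean, sd) per structure, inverted exactly into
  voxel counts V_right/left = V_total(1 ± LV)/2.  Defaults for (mean, sd)
  are the cohort values where reported — Th (−0.0123, 0.0121),
  CN (0.0115, 0.0285), Put (−0.0149, 0.0285), Acc (−0.1141, 0.0746) — and
  zero-mean with comparable spreads for the structures without robust
  lateralization: GP (0, 0.030), Hipp (0, 0.020), Amyg (0, 0.030).  Voxel
  counts are stored as floats: rounding to integers would break the exact
  LV round-trip that the generator guarantees and that the tests rely on.
* **Coupling.** HLM = β0 + Σβ_s LV_s + ε with defaults β = (−2.19, 0.92,
  0.51) for (Th, CN, GP), zero elsewhere, and ε ~ Normal(0, 0.049).  The
  noise sd was calibrated by Monte Carlo so the mean adjusted R² of the
  three-structure model at n = 33 is ≈ 0.38, the effect size the default
  conditions are meant to represent.  Condition-wise targets default to the
  overall HLM plus mean-centered Normal(0, 0.02) perturbations (so the
  equal-weight condition average equals the overall target); a second mode
  gives each condition its own (β0, β) — used to emulate
  condition-specific structure involvement (e.g. thalamus in the easiest
  condition, pallidus at intermediate load, caudate in the hardest).
  The perturbation sd is a free parameter with no empirical anchor.
* **Epochs.** At hotspot pair locations (first 5 of 8 pairs by default) the
  target trial-averaged MI in condition c is +m + h_c/2 on the right and
  −m + h_c/2 on the left (m = 0.2, a typical attentional modulation depth),
  so right-ROI mean + left-ROI mean recovers h_c; remaining pairs carry
  25% of the target, giving ROI selection its spatial contrast.  A target
  MI maps to per-side alpha power 1 ± MI (power ratio (1+MI)/(1−MI)),
  realized as an amplitude-scaled 10 Hz sinusoid.  Each location drives two
  planar channels with cos θ/sin θ amplitude weights (θ fixed per location)
  so the planar power sum restores the full amplitude².  Phases within each
  (condition, cue side) cell are evenly spaced on the circle, which cancels
  the phase-dependent interference term of windowed-sinusoid power exactly;
  with zero background noise the pipeline therefore recovers target MIs to
  machine precision, and the 1e-3 recovery tolerance in the tests is
  dominated by rounding alone.  Background noise is 1/f-power-spectrum
  broadband noise, unit variance per trace, scaled by a configurable
  amplitude (default 0.5 of the alpha carrier).
* **Behavior.** Accuracy is Bernoulli with side-dependent probability
  base ± d/2 (d = side bias, optionally LV-coupled); RT is log-normal with
  side-dependent location μ ± e/2.  Defaults: 80% accuracy, no bias,
  median RT 0.55 s, σ_log = 0.2.
* **Scale and timing choices.** Sampling rate defaults to 200 Hz (not a
  typical 1 kHz acquisition rate) so the 10-ms TFR step is exactly 2
  samples; the epoch window defaults to −1.5–0.5 s rather than a full
  −3–1 s acquisition epoch since the analysis uses only −850–0 ms.  Both
  are configurable; alpha-band content is far below Nyquist either way.
  Delay-period jitter is not simulated — modulation is stationary across
  the analysis window, which is all the pre-target analysis consumes.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: realistic sensor geometry and field spread
(locations are abstract mirror pairs), eye movements and artifacts,
evoked responses, non-stationary or rhythmically structured modulation,
inter-sensor noise correlations, and any deviation from linear
LV→HLM coupling.  Recovery results certify the pipeline's correctness, not
the biological model.

## Calibration and recovery studies

`alphalat.calibration` runs the statistical audits at truth level (LVs and
HLM targets drawn directly, no spectral stage, which the unit tests cover
separately):

* **Type-I error.** Under a no-coupling generator at n = 33, the overall
  GLM F test, the Hotelling per-regressor test, and the Wilks full(7) vs
  reduced(4) comparison each reject at α = 0.05 at the nominal rate
  (measured ≈ 0.047–0.059 over 1000–2000 replicates).
* **Coefficient recovery.** Under the default coupling at n = 33, mean
  estimates over 500 cohorts are unbiased well within 10% and 95% CI
  coverage is nominal.
* **Exact-subset recovery.** At n = 200 with the default (strong) coupling,
  the AIC-ranked exhaustive search selects exactly {Th, CN, GP} in ≈ 50%
  of replicates — the theoretical ceiling, since each of the four
  irrelevant regressors enters an AIC-minimal subset with probability
  ≈ P(χ²₁ > 2) ≈ 0.157 regardless of sample size or effect strength
  (0.843⁴ ≈ 0.50).  The BIC-ranked search, whose penalty grows with log n,
  recovers the exact subset in ≈ 90% of replicates at the same n.  This is
  an inherent property of AIC, not an implementation artifact; the
  package asserts the BIC behaviour as its recovery guarantee.

## Numerical and degenerate-input conventions

* Exact fits (zero residual) report R² = 1, infinite F, and undefined
  information criteria rather than raising.
* Rank-deficient designs, zero-variance regressors, nonpositive powers or
  voxel counts, empty trial selections, missing hemisphere rows, conditions
  with a missing cue side, and out-of-range Shapiro–Wilk sample sizes are
  all errors that name the offending object.
* Frequencies whose 3-cycle window exceeds the epoch yield NaN at every
  center (flagged missing, not silently dropped).
* All generator outputs are pure functions of (config, seed); cohort files
  are byte-identical across re-runs, and the pipeline report is
  byte-identical for a fixed config, which the test suite asserts.
* Monte-Carlo problem sizes in the tests and the acceptance script (cohort
  sizes 14–33 subjects for spectral-stage tests, 1000–2000 replicates for
  calibration, 100–500 for recovery) are the package's chosen desk-scale
  defaults; all are arguments that scale up.

## Known limitations

* The Rao F approximation for Wilks' Λ is approximate for four outcomes
  with hypothesis df ≥ 3 (measured null rejection ≈ 0.05–0.06 at n = 33).
* The Hotelling per-regressor test requires n − k − 1 ≥ p; the full
  7-regressor multivariate model needs n ≥ 12 for a nonsingular residual
  covariance with four outcomes.
* Sensor-level analysis only; no source modelling, no real MEG file-format
  ingestion (the `EpochSet` container plus the HDF5 reader form the
  documented adapter point).
* Condition-wise HLM(α) reuses the all-trials ROI by design; if the true
  spatial topography differs across conditions this choice underestimates
  condition-specific modulation.
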