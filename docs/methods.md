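# Methods

## Model

`pelbayes` implements the Gaussian ideal-observer account of perceived eye
level (PEL). The observer's belief about elevation is the normalized
product of a body prior N(μ_b, σ_b²) and one visual likelihood
N(θᵢ, σ_vi²) per pitched line; the posterior mean μ_p is the predicted
setting. Everything downstream — calibration, regime analysis, the
simulator — is exact algebra on this product-of-Gaussians form, carried
internally in variances (deg²) with standard deviations only at the API
surface, to avoid repeated squaring errors.

Assumptions worth stating explicitly:

- **Gaussianity.** Prior and likelihoods are Gaussian; no heavy-tailed or
  mixture extensions.
- **Geometric reading of pitch.** Each line's likelihood is centered on
  its pitch θᵢ: a line pitched by θ is interpreted as a vertical line seen
  from an eye level shifted by θ. Positive angles are upward; 0 is true
  eye level; everything is in signed degrees (no radian surface).
- **Conditional independence.** Lines contribute independent likelihoods,
  so precisions add.
- **Head fixed and upright.** Vestibular manipulations enter only as a
  shifted/broadened prior.

### Noise parameterizations

Two mutually exclusive visual-noise models live in `ModelParams`:

- a **per-length map** `length → σ_vi` (default prediction path,
  `predict_pel`): one separately calibrated noise per line length, mixed
  lengths rejected;
- a **length-free constant** σ_vl with σ_vi = σ_vl/√l
  (`predict_pel_varying`), which treats each unit of line length as an
  independent sample and supports mixed-length displays and unseen
  lengths.

The per-length path is the default because the √l independence assumption
degrades for long lines: calibrating k = σ_vl²/σ_b² from the short line
gives ≈ 72.7 while the long line gives ≈ 134. The package surfaces both
and never silently forces a single k. On the scaled path the prediction
collapses to μ_p = a(l) + Σθᵢ/(k/l + n) with a(l) = μ_b/(1 + n·l/k); a
property test asserts this compact form and the full fusion agree to
1e-9 for all tested inputs.

Uninformative beliefs are represented with infinite variance, which makes
their precision exactly zero (no large-sentinel tolerance bugs in the
limits). A zero-variance belief (constant calibration data) is kept
representable, flagged with a warning at the point it arises.

## Calibration

- **Prior:** sample mean and sample std (ddof = 1, the unbiased-variance
  small-sample convention) of dark-condition settings.
- **Visual noise:** OLS of mean PEL on pitch per line length
  (scipy.stats.linregress), then σ_v² = |σ_b²/m − σ_b²|. The regression is
  on condition means by default, matching how sweep data are usually
  reported; `raw=True` regresses on individual trials. A slope outside
  (0, 1) is inconsistent with the fusion model; the absolute value is
  applied with a warning, never a silent clamp, and m = 0 is an error
  (the cue had no measurable effect).
- The fitted intercept and the model-implied intercept (1 − m)·μ_b are
  reported side by side; empirical sweeps need not satisfy the implied
  relation and the package does not force agreement.

## Regime analysis

For each pitch on a grid, the single-line and two-line (same pitch)
predictions are expressed as shifts from the prior mean (so a nonzero μ_b
does not bias the statistic), and the two-line shift is regressed on the
sum of the single-line shifts. Because the model is exactly linear in
pitch, the regression slope equals the closed form
(σ_v² + σ_b²)/(σ_v² + 2σ_b²) to numerical precision; the regression is
retained as the estimator that also applies to empirical tables. The
labels additive-like (≥ 0.9) / averaging-like (≤ 0.6) / intermediate are
heuristic reporting conveniences only; the raw slope is always included.

## Simulator

`simulate_observer` draws each visually stimulated setting from the
posterior for its condition, N(μ_p, σ_p²) — the probability-matching
convention for an ideal observer — plus optional independent Gaussian
motor noise (default 0); dark settings are drawn from the prior. The
behavioral model itself does not constrain trial-to-trial variability, so
this response-noise assumption is a genuine modeling choice, and it
matters for parameter recovery: with posterior sampling the single-line
sweep slope is recovered unbiasedly by OLS on condition means.

The default design mirrors the classic two-length experiment: pitch grid
−30..30° in 10° steps, lengths 12° and 64°, two-line conditions with both
lines at the same pitch, 200 trials per stimulus condition. Dark trials
default to 2000, a size chosen by power analysis so that the sampling
error of the prior-std estimate (relative sd ≈ (2(n−1))^−1/2 ≈ 1.6%) sits
well inside the 5% band used by the recovery tests; at a few hundred dark
trials the σ_b estimate alone would consume most of that band. All
randomness flows through one `numpy.random.default_rng(seed)`; identical
seeds give bit-identical tables, and multi-subject batches derive seeds as
seed + subject index.

What the simulator deliberately does not emulate: adaptive/staircase
procedures, response times, lapses and attentional drift, sequential
dependencies between settings, and inter-subject variability within one
run. Passing recovery tests therefore show that the pipeline is correct
and well-conditioned under the model's own assumptions — not that real
observers satisfy those assumptions.

## Evaluation

The standard error of estimate (SEE) is the population RMSE
√(Σ(obs − pred)²/n); an `ddof` option provides the regression convention
(n − 2). Model comparison scores condition-mean observed PEL against both
the Bayesian prediction and the Matin–Li baseline
(PEL = a + k₁Σθᵢ/(k₂/l + n), constants taken as inputs with a per-length
offset a), with a per-trial option. Dark rows get the Bayesian prior mean
and no Matin–Li prediction (the baseline requires a line length); each
model's SEE is computed over the rows it predicts.

## Numerical choices

- Fusion is closed-form; the only numerics are OLS fits. Test oracles use
  brute-force grid integration of the density product (−90..90°, step
  0.001°, log-domain for underflow safety), independent of the closed
  form, and agree with it to 1e-6.
- Per-length lookups match lengths with isclose (rel/abs 1e-9) so CSV
  round trips cannot miss the map.
- Degenerate inputs: empty belief lists, all-uninformative fusions,
  identical-pitch regressions, zero slopes, negative noise, and
  mixed-length displays on the per-length path all raise informative
  errors rather than returning NaN.

## Problem sizes

The test suite and acceptance script run in seconds: grid-oracle checks
use 100 random parameterizations on a 180k-point grid; Monte-Carlo checks
use 10⁴ draws; recovery uses the default design above (about 36k trials).

## Known limitations

- The √l noise scaling is a rough approximation; extrapolation across a
  large length range with a single k is not supported by the calibrated
  values and should be treated with caution.
- Calibration is single-subject; hierarchical pooling across subjects and
  errors-in-variables regression are out of scope.
- One-dimensional elevation only; no azimuth generalization, no
  non-Gaussian beliefs.
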