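# Methods

## Problem and model

A qPCR amplification curve is a per-cycle fluorescence series; the *hook
effect* is a systematic cycle-to-cycle decrease in the late (plateau)
phase. `hookdetect` decides, per well, whether such a negative plateau
trend is statistically supported. Two routes are implemented and combined
by OR.

**Linear route.** After gating and normalization (below), the fluorescence
maximum at cycle x₀ splits the curve; the segment from x₀ (inclusive) to
the last cycle is fitted by OLS. Evidence is assessed through the slope's
one-sided lower-tail p-value (t distribution, m − 2 df) and its two-sided
CI at level 1 − α. A hook is called when p < α or the CI lies entirely
below zero; with the symmetric CI the p-rule is the weaker of the two, so
the OR is effectively governed by p < α. The segment must contain at least
`min_tail` = 5 cycles *after* x₀; shorter tails yield
`status = insufficient_tail` rather than a call, because a regression on a
handful of points selected at a running maximum is dominated by selection
bias.

**Nonlinear route.** The whole curve (minus the first `trim` = 5 baseline
cycles, removed so a sloping ground phase cannot leak into the drift term)
is fitted with the six-parameter log-logistic model

    y = c + k·x + (d − c) / (1 + exp(b·(log x − log e)))^f,

x > 0, e > 0, f > 0. With b < 0 the curve rises from baseline c to plateau
d; e is the inflection location (exact when f = 1); k is a linear drift
superimposed over the entire run. The CI of k̂ at level 1 − α uses the
Jacobian-based asymptotic standard error and the t distribution with m − 6
df; a hook is called when both CI bounds are negative. No p-value is
reported for k — the CI is the decision evidence.

## Preprocessing

*Normalization.* y′ = (y − min y) / q99(y − min y), with q99 the
linear-interpolation 99th percentile. This is a positive affine map, so
every decision is invariant under instrument gain and offset (a·y + b,
a > 0) by construction; normalization only fixes the scale on which slopes
are reported, making k comparable across wells and chemistries.

*Negative-reaction gate.* A reaction is negative when
(max y − min y) / σ̂ < `snr_min` (default 10), where σ̂ is the residual sd
about a straight line through the first 10 cycles. The detrending matters:
a pronounced hook measured without baseline correction has a visibly
sloping early phase, and a raw sd would count that trend as noise,
wrongly discarding exactly the curves the tool exists to find. A
zero-amplitude curve is negative by definition; zero early-phase noise
with positive amplitude is an infinite SNR (not negative). The gate is a
heuristic of this package (the decision to discard negatives is standard;
its specific form is ours) and both the window and threshold are
configurable.

## Parameters

| name | default | unit | meaning |
|---|---|---|---|
| `alpha` | 0.0025 | — | significance level; CI level 1 − α = 99.75% (bounds at 0.125% / 99.875%) |
| `min_tail` | 5 | cycles | cycles required after the maximum for the linear fit |
| `trim` | 5 | cycles | baseline cycles removed before the sigmoid fit (extendable) |
| `snr_min` | 10 | ratio | amplitude/noise threshold of the negative gate |

`alpha` defaults to 0.0025 (the stricter of the two levels in circulation
for this procedure; 0.005 is a common looser choice and is one flag away).

## Numerical choices

- **Optimizer.** `scipy.optimize.least_squares`, trust-region reflective,
  bounds f ∈ [10⁻³, 10³] and e within the observed cycle range, tolerances
  10⁻¹⁰, at most 1000 evaluations. Starting values: c₀ = min y,
  d₀ = max y, e₀ = cycle of the steepest single-cycle gain, f₀ = 1, k₀ = 0,
  b₀ = −10 with restarts at −5 and −20; the best (lowest-cost) converged
  solution wins. Non-convergence or a singular covariance maps to
  `status = fit_failed` and hook = False — plate-scale batch runs must not
  abort on one bad well.
- **Zero-residual guards.** A perfect linear fit has se = 0; by convention
  p = 0 for a genuinely negative slope, else 1, with the CI collapsing to
  a point. "Genuinely" means |slope| > 10⁻¹² × the response scale, so
  float noise on a constant tail is not maximal evidence. In the nonlinear
  route the residual sd entering the covariance is floored at 10⁻⁸ of the
  fluorescence scale: on noise-free data the optimizer's round-off in k̂
  (~10⁻¹⁰ or less) would otherwise be divided by an even smaller se,
  turning machine noise into a sign-definite CI. With the floor, exact-
  model data yields a CI that contains 0 unless the drift is real.
- **Tie-break.** The maximum is the *earliest* cycle attaining max y,
  which maximizes the tail length (conservative toward detection).
- **Degenerate inputs.** Flat curves (q99 of the shifted series = 0) are
  routed to `negative_reaction`; curves with fewer than 12 points after
  trimming cannot support a six-parameter fit and report
  `insufficient_tail`; m = 2 linear fits return the exact slope with
  undefined inference.

## Synthetic data

The generator draws curves from the same l6 surface the nonlinear detector
fits, plus homoscedastic Gaussian noise, in four shapes: `sigmoid`
(k = 0), `hook` (k < 0), `no_plateau` (inflection pushed to ≥ 95% of the
run, still rising at the last cycle) and `negative` (baseline + noise
only). The benchmark builder spans five classes — clean sigmoid, slight
hook (k ∈ [−0.008, −0.003]), pronounced hook (k ∈ [−0.02, −0.008]),
no-plateau, negative — with baseline ∈ [0, 0.2], amplitude ∈ [0.5, 3],
midpoint ∈ [15, 30] cycles, b ∈ [−15, −5], f ∈ [0.5, 2], 45 cycles,
noise sd 0.005 by default. These ranges are this package's construction,
chosen to mimic the qualitative repertoire of a mixed-chemistry plate.

Because generator and nonlinear detector share the model family, synthetic
benchmarks are a *best case* for `hookregNL`: they validate the inference
machinery (recovery, CI coverage, invariances, gating), not robustness to
model misfit. Real plates add baseline artefacts, heteroscedastic and
correlated noise, and hook shapes that are not exactly linear-in-cycle;
performance there is what the published 96-well benchmark measures, and
the linear detector — model-free apart from the tail-linearity
assumption — is the hedge against misfit. Test problem sizes (25–500
curves, 500 CI replicates, 10⁴ flat-plateau null curves) were chosen so
the full suite completes in about a minute while keeping Monte-Carlo error
well below the asserted margins.

## Known limitations

- The tail regression starts at the empirical maximum; on long flat
  plateaus this selection inflates the null false-positive rate by a small
  factor (empirically < 4× the nominal α; the strict default α absorbs
  this).
- The l6 fit can fail to converge on heavily distorted curves; such wells
  are reported, not guessed.
- The negative gate assumes ≥ 10 early cycles; very short runs fall back
  to a cruder noise estimate.
- No baseline correction, Cq estimation or efficiency analysis is
  performed or intended.
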