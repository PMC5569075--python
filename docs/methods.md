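# Methods

## The problem

When an observer adapts to an eight-pointed star whose points alternate
between two colors (e.g. red and green) and an outline is then drawn around
one sub-star plus the gray center, the afterimage of the center often fills
in with the outlined color even though the center was never colored. This
package implements the quantitative analysis of that *afterimage completion*
effect under the hypothesis that completion is gated by perceptual
transparency: the visual system decomposes the star into two overlapping
colored filter layers (scission), and only when the center luminance is
physically consistent with that layered interpretation does completion
occur.

## Transparency bounds

Treating each sub-star as a uniform neutral-density filter over the
background of luminance `L_bg`, the observed point luminance `L_pt` implies
a transmittance `T = L_pt / L_bg <= 1`. The center patch — background seen
through both filters — is then consistent with transparency only for

    B1 = T * L_pt = L_pt^2 / L_bg   <=   L_center   <=   L_pt = B2.

For the standard stimulus (`L_pt = 84`, `L_bg = 169` cd/m²) this gives
`[41.75, 84]` cd/m²; of the nine center luminances used in experiment 1
(0.1 … 169 cd/m², approximately log-spaced), exactly 54.9 and 83.7 fall
inside. The interval is treated as closed: a center exactly at a bound
still admits the layered reading. The point luminance is nominally 84 cd/m²
(the red/green equiluminance settings average ≈83.8); both bounds are
configurable.

## Completion models

Two piecewise-linear accounts of completion probability as a function of
log10 center luminance `L` are compared:

* **transparency model** — plateau `M` over `[B1, B2]`, descending with
  slopes `s1` (left) and `s2` (right) outside it;
* **equiluminance model** — the same family with a degenerate plateau,
  `B1 = B2 = E = log10 84`, i.e. a peak at equiluminance of center and
  points.

`M ∈ [0, 1]` and `s1, s2 >= 0` are free; the breakpoints are fixed physical
constants, not estimated. Log base 10 is used throughout; the base only
rescales slopes and leaves fit quality, BIC differences and weights
unchanged.

Because the breakpoints are fixed, both models are *linear* in `(M, s1,
s2)`: the predicted value is `M − s1·max(B1−L, 0) − s2·max(L−B2, 0)`. The
constrained least-squares problem is therefore convex and is solved exactly
by bounded linear least squares (`scipy.optimize.lsq_linear`); the fit is
deterministic and globally optimal, so no multi-start heuristic is needed.

Fits are scored by the full Gaussian BIC, `n ln(SSE/n) + n(ln 2π + 1) +
k ln n` with `k = 3` (the residual variance is not charged; since `k` and
`n` are equal across the two models, this choice cannot affect any
comparison). Schwarz weights `w_i ∝ exp(−ΔBIC_i/2)` give posterior model
probabilities under equal priors, and BIC differences are labelled on the
conventional evidence scale (<2 barely worth mentioning, 2–6 positive,
6–10 strong, ≥10 very strong). Models are fit to the across-subject mean
completion proportion at each of the 9 luminance levels (`n = 9`);
subject-level fitting is possible through the same function by passing a
longer table.

A zero-residual fit makes the Gaussian BIC degenerate; it is reported as
−∞ with a warning rather than an error, since it can arise legitimately on
noise-free synthetic data.

### Identifiability caveat

The two models differ only in whether the maximum is a 0.30-log-unit
plateau or a point, and just two of the nine design luminances fall on the
plateau. With residual noise of σ≈0.05 on the 9 group means the models are
therefore only weakly discriminable: simulation (see `tests/`) puts the
probability of the true model winning the BIC comparison near 0.5–0.7, and
even σ = 0.01 does not push the paper-like asymmetric case past 90%.
Decisive selection of the kind the published ΔBIC = 6.21 reflects requires
the empirical curve shape (a broad flat top well below the equiluminance
point) together with low residual noise. The model-comparison machinery is
exact either way; the caveat concerns the power of the design, and the
corresponding power assertions in the acceptance suite document the
measured rates.

## Mixed model and supporting statistics

The quadratic dependence of completion on luminance is tested with a
random-intercept model on per-subject per-level proportions, `y = β0 +
β1·x + β2·x² + b_subj + ε` with `x` the coded level 1–9. Estimation is
direct maximum likelihood of the closed-form Gaussian marginal likelihood:
the per-subject covariance `σ²I + τ²J` is inverted analytically (Woodbury),
β and σ² are profiled out, and a single 1-D optimization over the variance
ratio `θ = τ²/σ²` (coarse log-grid then bounded refinement, with the θ = 0
boundary checked explicitly) completes the fit. ML rather than REML is used
so the quadratic-vs-linear likelihood-ratio test (χ² with 1 df) is
self-consistent. The implementation agrees with an independent
mixed-model routine (statsmodels `MixedLM`, ML) to ≈1e-4 on shared test
data. The fitted parabola's vertex `x* = −β1/(2β2)` (requiring β2 < 0) is
mapped to cd/m² by linear interpolation of log10 luminance between
adjacent coded levels, the natural inverse of the approximately log-spaced
design; `x*` outside the 1–9 range clamps to the end levels.

t-tests are classical one-sample/paired tests; paired data are reduced to
differences, Cohen's d follows the `d_z = mean(diff)/sd(diff)` convention
(consistent with `t/√n`), one-sided p-values are taken in the direction the
caller requests (never inferred from the sign of t), and the 95% CI of the
mean difference is always two-sided. Zero-variance data yield `t = 0,
p = 1` when the mean equals the null and an infinite-t sentinel (with a
warning) otherwise.

Central tendencies of bounded proportions are summarized by the mode of a
maximum-likelihood beta fit. Exact 0/1 observations are first shrunk with
`p' = (p(n−1) + 0.5)/n` so the likelihood stays finite; the mode is
`(a−1)/(a+b−2)` when both shapes exceed 1 and otherwise the boundary at
which the fitted density diverges. Pearson correlation uses the standard
product-moment formula with a two-sided t-based p on `n − 2` df.

## Synthetic experiments

The generator reproduces the statistical skeleton of the three experiments
so the full pipeline can be exercised and calibrated without human data.
Its defaults are the study conditions:

| parameter | default | source/rationale |
|---|---|---|
| subjects (exp 1/2/3) | 12 / 20 / 16 | retained sample sizes |
| trials per condition | 20 | stated experiment-3 repetition count, reused for 1–2 (not reported there) |
| plateau `M` | 0.54 | peak condition mean |
| slopes `s1`, `s2` | 0.09, 0.85 | chosen so the extreme-luminance means are ≈0.30 and ≈0.28 |
| no-afterimage rate | 0.15 | luminance-independent baseline; per-condition rates unreported |
| subject-intercept SD | 0.15 | produces between-subject spread of the observed order on the probability scale |
| exp 2 condition probabilities | 0.46 / 0.16 | reported condition means |
| exp 3 link | `p = clip(0.05 + 1.0·completion + N(0, 0.08), 0, 1)` | yields strong positive rating–completion correlation of the observed order |

Subject heterogeneity acts additively on the probability scale with
clipping into `[0, 1 − p_no_afterimage]` — matching the analysis' linear
treatment of proportions — rather than through a logit link. Experiment 2
uses 8 conditions (two bicolor schemes × two outlined sub-stars, plus four
uniform colors), giving the 8-stimulus family the experiment-3 correlation
expects alongside the 9 luminance conditions of experiment 1. Responses are
multinomial draws per trial; everything is reproducible from one integer
seed via `numpy.random.default_rng`.

What the generator does *not* emulate: adaptation dynamics, reaction
times, eye movements, luminance-dependent lapse rates, any perceptual
mechanism. Passing tests therefore certify the statistical machinery and
its calibration under the assumed response model, not the perceptual claims
themselves.

## Pipeline

`analyze_exp1/2/3` chain the predetermined exclusion rules (experiment 1:
drop subjects with a no-afterimage fraction strictly above 2/3;
experiment 2: strictly more than 120 no-afterimage trials), aggregation to
per-subject condition proportions (with across-subject mean and s.e.m.),
and the statistics above, and return a self-contained report whose JSON
serialization is byte-stable for identical inputs (sorted keys, no
timestamps; provenance carries a config hash and the package version). No
multiple-testing correction is applied anywhere, and that fact is recorded
in report metadata. The experiment-1 paired contrasts use the printed
nominal labels (34, 55, 121, 169) mapped to the exact levels (34.1, 54.9,
121.4, 169.0).

## Rendering

Star rendering is illustrative and affects no statistic. The geometry is a
regular 8-pointed star made of two interleaved 4-pointed stars spanning the
stimulus diameter (4.3° at a configurable 60 px/°), with the center patch
the octagon where the sub-stars overlap (inner radius 0.35 of the outer).
Colors are specified as CIE xyY and converted through a standard
XYZ→sRGB transform with the brightest scene luminance mapped to display
white — an approximation, documented as such. The mask is a seeded uniform
random pixel array over the star's bounding box; mask rendering is
deterministic given the seed and inducer/outline rendering is
seed-independent. Images use a top-left origin, row-major.

## Problem sizes

Calibration checks in the test and acceptance suites use 100–500
replicates (500 for the likelihood-ratio type-I error, 200 for fit
recovery, selection power and experiment-2 power, 100 for the
experiment-3 link), sizes at which the binomial uncertainty on the
measured rates is a small fraction of the asserted margins.

## Known limitations

* No binomial/logit GLMM variant; proportions are modelled as Gaussian.
* Breakpoints are never estimated from data.
* The beta fit assumes an unimodal sample; bimodal proportion samples are
  summarized by whichever boundary dominates.
* Rendering chromaticity is display-agnostic sRGB, not a calibrated match
  to any monitor.
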