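# Methods

This note documents the models, statistics and design choices behind
`qpcrbench`: how threshold cycles are estimated from raw amplification
curves, how estimation methods are scored against a mixture/dilution
benchmark design, and what the synthetic data generator does and does not
emulate.

## Background and data model

Quantitative PCR reports one baseline-corrected fluorescence reading (ΔRn)
per amplification cycle. The more abundant the target, the earlier the
fluorescence rises, so the *threshold cycle* — the fractional cycle at which
amplification is considered detected — is a (negative, logarithmic) proxy
for abundance: one cycle less means roughly twice as many starting copies.
Throughout the package, "expression" means a threshold cycle, so **lower
values mean higher abundance**, and every estimate is paired with a quality
score for which **higher is always better**.

The benchmark design blends two heterogeneous RNA pools (A and B) into ten
sample types, each measured in quadruplicate (40 samples), with weights
expressed relative to a pure sample:

| type | (w_A, w_B) | role |
|------|-----------|------|
| 1    | (1, 0)    | pure A |
| 2–4  | (1, 0.2), (1, 0.4), (1, 0.8) | series titrating B |
| 5    | (0, 1)    | pure B |
| 6–8  | (0.2, 1), (0.4, 1), (0.8, 1) | series titrating A |
| 9    | (0.1, 0.1)   | ten-fold low-input dilution |
| 10   | (0.01, 0.01) | hundred-fold low-input dilution |

The titrated weight doubles twice along each series (16, 32, 64 volume
units against a constant 80), i.e. ratios exactly 1:2:4.

## Curve models and the cpD2 estimator

Five parametric families are fitted by bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective):

- `b4`: f(x) = c + (d − c) / (1 + exp(b (x − e)))
- `b5`: as `b4` with the denominator raised to an asymmetry exponent *f*
- `l4`: f(x) = c + (d − c) / (1 + exp(b (ln x − ln e)))
- `l5`: as `l4` with exponent *f*
- `linexp`: f(x) = a·exp(k x) + m x + o

Parameters: b (slope; negative for a rising curve), c/d (lower/upper
asymptotes, fluorescence units), e (location, cycles), f (dimensionless).
Starting values are taken from the data: c₀ = min ΔRn, d₀ = max ΔRn, e₀ at
the steepest observed rise, b₀ from the finite-difference slope there
(scaled by e₀ for the log-cycle families), f₀ = 1. Bounds enforce c < d and
b < 0. A fit is *non-converged* — not an error — when the data have zero
variance, the optimizer fails or exhausts its 500-evaluation budget, or the
fitted curve does not rise meaningfully (total rise ≤ 10⁻⁶ of the data
span) across the cycle window; its estimate is then missing and its quality
score 0.

The expression estimate is **cpD2**: the cycle in [1, C] at which the
second derivative of the fitted curve is maximal. Second derivatives are
analytic for every family. For `b4`/`b5` the argmax itself has a closed
form: d(f″)/dx = 0 reduces to f²z² − (3f+1)z + 1 = 0 in z = exp(b(x−e)),
whose larger root z* gives x* = e + ln(z*)/b (for f = 1, z* = 2 + √3, the
classic logistic result x* = e − s·ln(2+√3) with s = −1/b). For the
log-cycle and linexp families the argmax is located on a 0.01-cycle grid
and refined with a bounded scalar minimizer (tolerance 10⁻¹⁰), accurate to
well below 10⁻³ cycles. For `linexp` the second derivative a·k²·e^{kx} is
monotone, so its cpD2 sits at the cycle-window boundary; the family is kept
for completeness and its poor behaviour is itself informative. The fit's
quality score is R² = 1 − SS_res/SS_tot on the fitted cycles.

## Expected expression under mixing

All comparisons against "truth" use the abundance-scale mixing model: a
sample with weights (w_A, w_B) has expected expression

    E = −log2( w_A·2^(−E_A) + w_B·2^(−E_B) )

where E_A, E_B are the feature's pure-pool threshold cycles (replicate
means over good-quality estimates of types 1 and 5). A zero weight removes
its term regardless of the pure value; a missing pure value with a positive
weight makes the expectation missing; an infinite pure value encodes
absence from that pool (zero abundance). A direct consequence used as a
self-check: scaling both weights by 1/10 raises E by exactly log2 10 ≈
3.3219 cycles.

## The seven assessments

Unless noted, "good quality" means quality ≥ threshold (inclusive; default
R² ≥ 0.99, and 1.25 is the conventional cut for imported vendor AmpScores),
and observed values are means over good-quality replicates.

1. **Quality summary** — pairs every present estimate with its quality
   score, reports the quality distribution of missing-expression entries,
   and bins the 2-D (expression, quality) cloud.
2. **Expression comparison** — pairs two methods' estimates entry-wise,
   restricted by default to entries good under *both* methods
   (`restrict="present"` relaxes this), and flags |e₁ − e₂| above a
   threshold (default 2 cycles ≈ 4-fold abundance).
3. **Complete features** — per method, a feature is *complete* (present and
   good in all 40 samples), *absent* (in none) or *partial* (otherwise);
   the two-method 3×3 cross-tabulation comes with margin/total identities.
4. **Limit of detection** — three comparisons: type 9 and type 10 against
   the pure-pool expectation, and type 10 against type 9 shifted by
   log2 10. For each tolerance t ∈ {0.5, 0.75, 1.0} the reported threshold
   is the smallest observed expected-expression value t* such that the
   median |observed − expected| among features with expected ≥ t* is ≥ t
   (scanned over the sorted expected values, no interpolation; missing if
   never reached). This first-crossing rule is deterministic and makes the
   threshold non-decreasing in the tolerance by construction. Replicate
   groups with no good replicate are dropped from the scan and show up in
   the per-feature proportion-poor-quality column (values 0, ¼, ½, ¾, 1).
5. **Titration response** — a feature *responds* in a series when its
   replicate-mean expression is strictly decreasing (abundance strictly
   increasing) along the three doubling steps; ties count as non-response,
   which keeps the criterion conservative and deterministic. Results are
   stratified by d = (constant component's pure expression) − (titrated
   component's pure expression), so d > 0 means the titrated component is
   the more abundant one.
6. **Accuracy (signal-detect slopes)** — per feature and series, ordinary
   least squares of observed on expected expression; the ideal slope is 1.
   The regression uses replicate-level good-quality points (up to 12 per
   feature/series) rather than three means, giving the slope-zero t-test
   usable degrees of freedom; features with p ≥ 0.05 are flagged
   non-significant (no multiplicity correction — the flag is descriptive).
   Slopes need ≥ 3 points and ≥ 2 distinct expected values. The summary
   reports median and MAD (normal-consistent, R convention) in tertiles of
   d, pooled over both series.
7. **Precision** — per feature × sample type, the within-replicate SD
   (n − 1 denominator) and CV = SD/mean, computed when at least two
   replicates are present and every present replicate is good quality;
   summarized in three equal-count bins of the group mean.

## Synthetic benchmark generator

The generator exists so every estimator and assessment is testable without
external data. Per feature it draws pure-pool threshold cycles uniformly on
(14, 30) cycles, with 15 % of features A-only, 15 % B-only and 15 % absent
from both pools (the remaining 55 % shared, independent draws) — mirroring
the mix of tissue-specific and undetectable species in the real two-pool
design. Curve shape per feature: plateau U(1.5, 4) fluorescence units,
baseline U(0, 0.1), slope scale s U(1.5, 2.5) cycles.

Every curve is a symmetric logistic anchored so that its analytic cpD2
equals the target threshold cycle: x_mid = ct + s·ln(2+√3). Mixture cycles
follow the abundance-mixing formula above; replicate jitter is Gaussian
(default σ = 0.25 cycles); fluorescence noise is i.i.d. Gaussian per
reading (default σ = 0.05, absolute); a small fraction of curves
(default 1 %) fail outright and stay flat.

The detection limit is modelled at the single-molecule level: the template
copies in a reaction are Poisson with mean 2^(M − ct), where M (default 32
cycles) is the cycle at which one copy is expected. Zero copies mean
dropout (a flat curve) — so the dropout probability exp(−2^(M−ct)) rises
sigmoidally past M — and a detected reaction amplifies from its *realized*
copy number, ct = M − log2(n). Observed expression therefore saturates near
M and grows noisier as abundance falls, which is exactly the
observed-vs-expected divergence the limit-of-detection assessment
quantifies; with the detection limit at M, the tolerance-0.75 threshold of
a comparison whose expected values cross M lands within about a cycle of M.
The plateau additionally decays as exp(−0.015·max(0, ct − 20)), so late
curves have lower signal-to-noise and earn lower R² — reproducing the
empirical quality-versus-expression gradient. Setting every noise term to
zero (`NoiseConfig.noiseless()`) makes the pipeline exactly invertible:
fitting `b4` recovers every true cycle to numerical precision, all
signal-detect slopes are 1, all CVs are 0.

All randomness flows from one integer seed through `numpy`'s PCG64
generator with vectorized, shape-fixed draws, so results are independent of
iteration order and bit-reproducible.

### What the generator does not emulate

No chemistry-level effects: amplification-efficiency drift, primer
cross-hybridization, pre-amplification bias, baseline drift or well
position effects. Curves are exactly logistic, so passing recovery tests
shows the estimation and assessment machinery is correct, not that any
model family fits real amplification shapes best. In particular the
log-cycle `l4` family, fitted to symmetric-logistic curves, carries a small
systematic cpD2 offset (median ≈ 0.3 cycles here); on real data the
corresponding convention difference (raw- vs log-cycle axis) likewise
shifts estimates slightly between implementations.

## Numerical choices and degenerate inputs

- Fit tolerances 10⁻¹⁴ (ftol/xtol/gtol), max 500 residual evaluations.
- Detection pre-filter: curves whose fluorescence-cycle Pearson correlation
  is below 0.35 are flagged non-converged without running the optimizer. A
  genuine amplification trace — even a late partial rise — correlates far
  above this; a pure-noise trace scatters around 1/√C ≈ 0.15, and fitting
  such traces costs two orders of magnitude more time than a real fit only
  to produce an estimate that quality filtering discards anyway.
- Zero-variance curves, non-rising fits and optimizer failures are
  non-converged; R² undefined ⇒ quality 0.
- cpD2 is clipped to the observed cycle window [1, C].
- The LOD scan uses observed expected values as candidates; equal
  candidates are scanned once.
- Tertile/equal-count bins use quantile cuts with duplicate edges dropped;
  bins are only reported when at least three groups exist.
- Exponentials are clipped at ±700 to avoid overflow for extreme
  parameters.

## Problem sizes used in the checks

The default test suite simulates 60-feature (noise-free, end-to-end fit)
and 500-feature (jitter-only, assessment statistics) benchmarks plus
constructed toy matrices; these sizes were chosen as the smallest at which
every stratified summary (tertiles, ten quantile bins) is well populated.
The acceptance script runs the full 754 × 40 × 46 design with both `b4`
and `l4`.
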