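# Methods

## P-value models under the alternative

A one-sided z-test of H: μ = 0 against a standardized shift δ ≥ 0 yields
the p-value P = 1 − Φ(X) with X ~ N(δ, 1). Its density on (0, 1) is
h(p) = φ(Φ⁻¹(p) + δ)/φ(Φ⁻¹(p)), its CDF is Φ(Φ⁻¹(p) + δ), and for every
δ ≥ 0 it is stochastically smaller than uniform: Pr(P ≤ p) ≥ p. δ = 0
recovers the uniform null distribution. The mean has the closed form
E[P] = Φ(−δ/√2) (the probability that an independent standard normal
exceeds X), which we use to validate the quadrature.

The step-function approximation replaces h by a two-level density: height
f on [0, t] and height g on (t, 1], with 0 ≤ g ≤ 1 ≤ f and breakpoint
t = (1 − g)/(f − g) fixed by normalization. Its moments are
E[P] = (1 − 2g + fg)/(2(f − g)) and E[P²] = (g + (f − g)t³)/3, the latter
obtained by integrating p²h(p) directly. A closed-form variance
expression sometimes quoted for this family is inconsistent with the
moment table the calibration reproduces (it gives SD ≈ 0.65 instead of
0.274 at f = 1.728, g = 0.555, apparently a typographical corruption of
exponents), so the implementation derives the variance from the density
and validates it against the table. The single-parameter model is the
g = 0 case: all mass on [0, 1/f], E[P] = 1/(2f), var[P] = 1/(12f²); f = 1
is the uniform null and f → ∞ approaches the Dirac–uniform configuration
(point mass at zero), which retains no effect-size information.

Joint models for n hypotheses are products of independent univariate
components, possibly with different parameters per component.

## Calibration

`match_mean(delta)` sets 1/(2f) equal to the normal-model mean, computed
by adaptive quadrature of ∫Φ(x)φ(x + δ)dx over the real line with
absolute tolerance 1e−10 (cross-checked against Φ(−δ/√2) in the tests).

`match_mean_variance(delta)` solves the two moment equations. The mean
equation is linear in f given g, f(g) = (1 − 2g + 2μg)/(2μ − g), leaving
a one-dimensional root find in g for the variance equation, bracketed on
[0, min(1, 2μ)) — the upper limit is where f(g) diverges — and solved by
Brent's method with xtol 1e−14. This is derivative-free and robust; the
variance residual changes sign on the bracket for every δ > 0 tested
(the g = 0 endpoint gives SD μ/√3, below the normal model's SD, the
upper endpoint gives SD at or above it). δ = 0 is degenerate — every
moment-matched model collapses to the uniform — and returns the uniform
model carrying an explicit `degenerate` flag instead of an
ill-conditioned (f, g) pair.

Sampling uses inverse-CDF transforms for the step models and the tail
transform P = Φ(−(Z + δ)) for the normal model, one `numpy` generator
per call seeded by a single integer; product models spawn one child seed
per component.

## Two hypotheses: exact size and optimal constants

For n = 2 the exact-size condition under independent uniforms reduces to
(1 − 2c₂) + c₁(2c₂ − c₁)α = 0, i.e. c₂ = (1 − c₁²α)/(2(1 − c₁α)).
Requiring c₁ ≥ c₂ ≥ 0 confines c₁ to [1, 1/√α]: c₁ = 1 forces the Simes
pair (1, ½) and c₁ = 1/√α forces c₂ = 0. On that interval c₂ is strictly
decreasing in c₁, so exact-size pairs form a one-parameter family.

With single-parameter step models of heights f₁ ≤ f₂, the rejection
probability is piecewise polynomial with three branches separated by
1/(c₁α) and 1/(c₂α) and saturating at one. Maximizing over the
exact-size family gives, for one false null at effect f:

- small effects, f ≤ 1/√α: maximal power fα at (1/√α, 0);
- moderate effects, 1/√α < f ≤ (1 + √(1−α))/α: maximal power
  (1 + f²α)/(2f) at c₁ = 1/(fα), c₂ = (f²α − 1)/(2αf(f−1));
- large effects: power one for every pair with c₂ ≥ 1/(fα). The
  published analysis leaves the choice open here ("different tests have
  similar power"); this package returns the exact-size pair with
  c₂ = 1/(fα), the smallest c₂ achieving full power, as a deterministic
  convention.

With both nulls false, (1/√α, 0) is uniformly best and the maximal power
is f²α ∧ 1. Both maxima are continuous across regime boundaries, which
the tests check explicitly.

The normal-model analogue substitutes the constraint into the closed
reduction of the rejection-region double integral,
c₁α·Φ(Φ⁻¹(c₁α)+δ) + c₂α(1−Φ(Φ⁻¹(c₁α)+δ)) + (1−c₁α)Φ(Φ⁻¹(c₂α)+δ),
and maximizes over c₁ ∈ [1, 1/√α] with a 200-point grid pre-scan
followed by bounded scalar minimization (xatol 1e−8 or better); the
pre-scan guards against the mild regime kinks. δ = 0 makes the objective
identically α; the Simes pair is returned with a degeneracy flag.

## The B-table recurrence for general n

B(n, m, i) is the probability that, scanning the ordered p-values from
the largest down, the first index with p₍ₙ₋ᵢ₊₁₎ ≤ cᵢα is i (with
i = n + 1 meaning no index qualifies). These events partition the sample
space, power is Σᵢ₌₁ⁿ B(n, m, i), and m = 0 yields the type-I error.
Conditioning on whether the smallest p-value belongs to a true or a
false null gives the recurrence quoted in the README, with base cases
B(1,0,1) = c₁α ∧ 1 and B(1,1,1) = fc₁α ∧ 1 and their complements. (One
published listing of the base cases repeats the label B(1,0,2); the
fourth entry is read as B(1,1,2) = 1 − (fc₁α ∧ 1), the only completion
consistent with the partition.)

Implementation: a dynamic program over sub-problems (n′, m′), n′ = 1…n,
m′ = 0…min(m, n′). For rejection index i the recursion references the
layer-(n′−1) entry at the same i; when i = n′ that entry is the
accept-all probability of the (n′−1)-hypothesis sub-test, which is
stored as the exact residual 1 − Σᵢ B(n′−1, m′, i), keeping every layer
summing to one to machine precision. Entries are clamped into [0, 1]
after each step to absorb rounding. Both c_iα and fc_iα are capped at
one, so constants above 1/α are legal and inert under the null.

The factorization behind the recurrence presumes monotone constants
c₁ ≥ … ≥ cₙ (for a non-monotone set the branch events no longer
decompose, and the recurrence overcounts). Since a non-monotone set
defines exactly the same rejection region as its monotone
canonicalization, `build_b_table` canonicalizes its input first; the
result is exact for arbitrary constant sets, which a Monte-Carlo test
confirms on a deliberately non-monotone example.

Power is one whenever f ≥ 1/(c₍ₙ₊₁₋ₘ₎α) with c₍ₙ₊₁₋ₘ₎ > 0 — every
false-null p-value then lands below its constant with certainty.

## Flat-top constants

The largest c with c₁ = … = c₍ₙ₊₁₋ₘ₎ = c (rest zero) controlling the
type-I error solves Pr(Bin(n, cα) ≥ m) = α. The tail is monotone in cα,
so the root is unique; it is found by Brent bisection on cα ∈ (0, 1]
with xtol 1e−14. The bracket deliberately starts below α: for m = 1 the
root cα = 1 − (1−α)^{1/n} lies strictly below α, so a bracket starting
at α would exclude it. The leading-term approximation is
c ≈ (C(n,m) α^{m−1})^{−1/m}, within 15 % of the exact root for n ≤ 6 at
α = 0.05, and the corresponding full-power effect threshold is
f ≳ (C(n,m)/α)^{1/m}.

## Monotone canonicalization

`canonicalize` performs one right-to-left sweep replacing each
cₖ < cₖ₊₁ by cₖ₊₁ (a suffix maximum). Each replacement leaves the union
defining the test unchanged, the sweep handles any number of violations
inductively, and the operation is idempotent. Tests verify power
equality through the recurrence to 1e−12 on random sets and the
dominance picture for n = 2: the equal-constants exactly-sized test is
strictly beaten by the strictly monotone optimum for all effect sizes
strictly between the null and the large-effect boundary
f = (1 + √(1−α))/α, with one false null; ties occur only at the
boundary (and trivially at f = 1, where every exact-size test has
power α).

## Monte-Carlo oracle

`empirical_rejection` draws p-vectors from a product model, sorts each
descending, and applies the elementwise comparison with cᵢα — a literal
transcription of the test definition, O(reps·n log n). The standard
error is the binomial √(p̂(1−p̂)/reps). Defaults: 10⁵ replicates; tests
pin seeds. Analytic results are accepted when within 3 standard errors.

## What the synthetic conditions do and do not show

All validation operates under the models' own assumptions: independent
p-values, one-sided normal test statistics with unit variance, a common
effect parameter f for all false nulls in the recurrence (heterogeneous
effects are exercised only through the n = 2 closed form and the
Monte-Carlo path). Passing tests therefore certify the internal
consistency of the calibration, closed forms, recurrence and simulation
— not robustness to dependent p-values, non-normal statistics (t,
chi-square, F), or composite alternatives, none of which are modelled
here. The step model is a two-moment approximation: its tail shape
differs from the normal-based density (Fig.-style CDF comparisons can be
produced with `cdf` on a grid), and optimal constants derived from it
are exactly optimal only within the step family.

## Problem sizes

The full test suite runs in well under a minute on one CPU: quadratures
are one- or two-dimensional, the recurrence is O(n²m) arithmetic, and
Monte-Carlo checks use 10⁵–2·10⁵ replicates for n ≤ 4 — ample for
3-standard-error agreement at the probabilities involved.
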