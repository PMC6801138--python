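# Methods

## The equal-copy pick null

The inferential core is the distribution of guide identities among k
clones picked uniformly **without replacement** from a pooled library
idealized as m distinct guides at exactly c copies each (N = m·c clones;
the screen's configuration is m = 260, c = 12, N = 3120, k = 5). The
multiplicity pattern of the picks — an integer partition λ of k — has
probability

    P(λ) = [ m! / (∏_j a_j! · (m − d)!) ] · ∏_i C(c, λ_i) / C(N, k)

with d = |λ| distinct guides among the picks and a_j the number of pattern
entries equal to j. The two extremes reduce to `C(m,k)·c^k / C(N,k)`
(all distinct, 0.965 at the screen's configuration) and `m·C(c,k) / C(N,k)`
(all same, 8.38 × 10⁻¹¹). Patterns demanding more than c copies of a guide
have probability zero by construction rather than raising.

The test verdict reports the observed pattern's exact probability and a
tail aggregating patterns *at least as concentrated*: strictly larger
maximum multiplicity, or equal maximum multiplicity with no larger
probability. The significance level is a parameter (default 0.05); the
all-same outcome rejects at any conventional level, the all-distinct
outcome retains.

**Numerics.** Probabilities are computed by exact integer arithmetic
(`math.comb` and `fractions.Fraction`) whenever the pool has at most
10 000 clones, which covers every realistic clone-picking screen; a
log-gamma path handles larger pools and is cross-checked against the exact
path in the tests. Pattern probabilities sum to 1 within 10⁻¹² over all
partitions of k.

## Library coverage

Per-guide coverage of a pool of N colonies over n equiprobable constructs
is `1 − (1 − 1/n)^N`, evaluated in log space (`expm1`/`log1p`) so N = 10⁷
does not underflow. The stricter "every guide present" probability is
provided by inclusion–exclusion as a convenience, but the design headline
is the per-guide number, which is the quantity the > 99.99% claim at
n = 260, N = 3000 refers to. `required_clones` inverts the bound in closed
form and then enforces two-sided minimality explicitly to be safe against
floating-point rounding at the boundary.

The idealized copies-per-guide of a pool (`n_clones / n_guides`) is
returned as an exact rational with an integrality flag: 3120/260 = 12
exactly, while the actually pooled 3000 colonies give 11.54, flagged
non-integer rather than silently rounded, since the pick null assumes an
integer copy count.

**TSS window convention.** Guide positions are stored as the offset of the
guide site to the transcription start site, negative upstream; the
activation-optimal window test uses the closed interval [−200, 0] bp. No
coordinate convention is universal here; this one is fixed and documented.

## Serial-passage screen simulator

No population-dynamics model is observable from a clone-picking screen, so
the simulator is the simplest mechanism that interpolates between the two
regimes such a screen distinguishes. One subculture = one growth step plus
one dilution:

1. expected counts are multiplied by each guide's fitness factor
   w_g^g_d, where g_d (`doublings`) converts a per-doubling advantage into
   a per-subculture factor (default g_d = 1, i.e. fitness is already the
   per-subculture factor);
2. the pool is diluted back to a fixed bottleneck size (default m·c) by
   **residual resampling**: the integer part of each guide's expected
   count is kept deterministically and only the fractional remainder is
   drawn multinomially.

After the last passage, k clones are picked without replacement from the
realized pool (sequential multivariate-hypergeometric draws).

Residual resampling, rather than a plain multinomial bottleneck, is a
deliberate design choice. A multinomial bottleneck adds with-replacement
sampling variance at every passage, so an initially equal-copy pool drifts:
after five neutral passages at bottleneck 3120 the probability that two
picks share a guide rises from (c−1)/(N−1) = 3.53 × 10⁻³ to ≈ 5.1 × 10⁻³,
visibly inflating coincidences relative to the equal-copy null. The
screen's own control-arm reasoning assumes an unselected library remains
evenly distributed across passages; residual resampling makes the neutral
dynamics exactly composition-preserving (a neutral passage of an
equal-copy pool is a no-op), so neutral picks provably follow the exact
null, while selection and picking remain fully stochastic. The plain
multinomial scheme is retained behind `resample="multinomial"` for
sensitivity analyses of drift.

**Regimes.** Neutral fitness reproduces the exact null (verified by
chi-square over 10⁴ simulated screens). The strong-selection analogue of
the selective culture uses a per-doubling advantage of 8 across 1:100
subcultures (g_d = log₂ 100 ≈ 6.64 generations per passage, the standard
serial-dilution ratio); the advantaged guide then sweeps from frequency
12/3120 ≈ 0.004 to ≈ 1 within five passages and all five picks carry it.
Note that a per-*subculture* factor of 8 alone is not enough for a full
sweep: the winner's final frequency would be 12·8⁵/(12·8⁵ + 3108) ≈ 0.992
and all-five-same picks would occur only ≈ 96% of the time, which is why
the per-doubling regime is the meaningful "strong selection" setting.
Dilution ratios and passage durations are config-exposed, not asserted.

## Logistic growth model

OD600 curves are fitted with y(t) = A₂ + (A₁ − A₂)/[1 + (t/x₀)^p] by
Levenberg–Marquardt least squares. Initialization: A₁ ← min(y),
A₂ ← max(y), x₀ ← first time the curve crosses the half-range, p ← 4;
three jittered restarts (seeded) guard against bad starts, and the best
residual wins. Positivity of x₀ and p is enforced by optimizing their
logarithms; A₂ ≥ A₁ is *not* enforced — decreasing signals fit with a
negative rate and are flagged via `decreasing`. R² is defined against the
mean-only model, 1 − SS_res/SS_tot; a zero-variance (flat) curve is an
error rather than a fit.

The growth rate is the model's closed-form derivative
(A₂ − A₁)·p·(t/x₀)^p / (t·[1 + (t/x₀)^p]²), verified against central
finite differences and against numerical quadrature (the rate integrates
back to the OD increment). For p > 1 the rate peaks at
t* = x₀·((p−1)/(p+1))^(1/p), verified against a grid argmax; for p ≤ 1 the
supremum is at t → 0⁺ and the function warns and returns 0 instead of
raising. Rate evaluation is restricted to t > 0, where the model is
smooth for all p.

Curves are fitted per well and aggregated as mean ± SD; nothing is pooled
before fitting.

## Assay quantification

**ΔΔCt.** Replicate Ct values are averaged within sample before
differencing: ΔCt = Ct(gene) − Ct(reference) per sample,
ΔΔCt = ΔCt(sample) − ΔCt(control), fold = E^(−ΔΔCt) with amplification
efficiency E fixed at 2 (ideal doubling; exposed as a parameter).
Replicate SDs propagate in quadrature onto ΔΔCt. Down-regulation is
reported by the reciprocal convention ("7.39-fold down" ⇔ fold = 1/7.39),
so `reported_fold ≥ 1` always.

**TBARS.** An OLS line through ≥ 3 calibration standards converts OD535 to
MDA concentration; the result is concentration × assay volume scaled to
10⁷ cells. The assay volume is a required input — it is not inferable from
a reading — and the unit convention is whatever the calibration's
concentration unit implies (µM standards with mL volumes give nmol per 10⁷
cells). Readings below the blank floor at zero with a `clipped` flag.

**FAME.** Species concentrations are peak areas relative to the internal
standard times its known concentration (unit response factors unless
supplied); fractions are normalized concentrations. UFA and mono-UFA
fractions sum the species with ≥ 1 and exactly 1 double bond respectively,
using a saturation annotation (defaults cover 16:0, 16:1, 18:0, 18:1 — the
Δ9-desaturase substrate/product pairs). Unannotated species are an error,
not silently dropped.

**Replicate statistics.** Two-sample two-sided Student's t test with
pooled variance (Welch behind a flag), significance at α = 0.05 by
default. Two zero-variance groups with equal means define p = 1. The
implementation is cross-checked against a quadrature oracle integrating
the t density from first principles, and its null type-I error rate is
simulation-checked at n = 3 per group.

## Synthetic data: what it does and does not emulate

The generators produce exactly the structures the quantification stages
consume, with known ground truth: logistic curves plus additive Gaussian
reader noise (default sd 0.02 OD, quadruplicate wells, hourly sampling
over 24 h); Ct tables where a fold change f shifts the treatment Ct by
−log₂ f around a shared reference; GC peak areas proportional to
concentration; TBARS readings on a known calibration line with standards
spanning the truths. They do **not** emulate amplification-efficiency
drift, pipetting covariance between replicates, GC response-factor
nonlinearity, chromatographic co-elution, evaporation or edge effects in
plates, or culture-to-culture biological variability. Passing round-trip
tests therefore demonstrates that the quantification arithmetic is exact
and stable under the stated noise, not that these models capture every
systematic error of the corresponding instruments.

## Problem sizes

The acceptance script evaluates the pick null in closed form (instant) and
fits 12 synthetic growth curves. The test suite runs the neutral-screen
chi-square at 10⁴ simulated screens, the strong-selection sweep at 10³,
Monte-Carlo checks at 10⁵ picks, and parameter recovery at 100 seeded
fits; the whole suite completes in well under a minute on one core.
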