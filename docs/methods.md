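# Methods

## Model and assumptions

The data are *t* repeated pairs (x_ik, g_ik) per subject: a continuous
objective outcome x (a disease-status measurement or its change from
baseline, in original units) and a binary g obtained by dichotomizing an
ordinal PRO at scale z (g = 1 iff PRO ≥ z; the raw PRO, not its change
from baseline, is dichotomized — a one-unit PRO change does not carry a
constant clinical meaning across the scale). The model assumes a
subject-specific latent threshold a_iz on the objective scale and one
probability Q_iz, identical on both sides of the threshold, that the
dichotomized PRO lands on the "true" side:

    Pr(g = 1 | x >= a_iz) = Pr(g = 0 | x < a_iz) = Q_iz.

The equal-probability assumption is load-bearing: with unequal
probabilities on the two sides the parameters are not estimable without
knowing their ratio and the per-visit marginal distributions of X, so
that extension is deliberately out of scope. A non-negative association
is assumed (Q ≥ 0.5); a negatively associated endpoint should be sign-
flipped first. No distribution is assumed for X or for a_iz, and visits
may be arbitrarily correlated — the estimator only tabulates per-visit
agreement.

## Estimation

A threshold grid {a_j, j = 1..m} is fixed **before** seeing the data,
from clinical knowledge of the plausible range of X (e.g. the normal
range of hemoglobin); its step sets the resolution of the threshold
estimate. At each a_j the t visits form a 2×2 table of x ≥ a_j against
g, with x = a_j counting as positive, and R_ij = (TP+TN)/t is the
agreement accuracy. E(TP+TN) is maximized at a_j = a_iz when Q > 0.5 and
equals tQ there, so Q̂_iz = max_j R_ij is consistent and TP+TN is
binomial(t, Q) at the true threshold; that binomial argument supplies the
variance Q̂(1−Q̂)/t and the Clopper–Pearson exact interval (appropriate
because t is small in practice). Under no association every R_ij is
unbiased for 0.5 and the maximum is badly biased upward, so a separate
median-of-R rule serves that regime.

Numerical choices:

- Tie detection among R values compares the integer TP+TN counts, never
  floats (R is rational with denominator t).
- Tied maxima: â is the median of the tied grid points; for an even tie
  count, the mean of the two middle points.
- Median rule with even m: mean of the two central order statistics of
  R. The reported â under the median rule (median of the grid points
  whose count is nearest the median; the smaller achieved count on an
  exact tie) is **not identified** — under no association there is no
  threshold to find — and is reported for symmetry only.
- Median rule CI: the binomial success count is round(q̂·t). This is an
  explicit approximation; the binomial argument is exact only at the true
  threshold.
- Grids built from (min, max, step) are generated by integer index
  (min + j·step) to avoid cumulative floating-point drift; the last point
  is included iff it lands within half a step of max.
- Subjects with constant x or constant g are estimable but weakly
  identified; they trigger a logged warning, and population summaries
  apply (by default, and optionally) an eligibility filter requiring at
  least one g = 1 and ≥ 2 distinct x values.

## Multi-subject inference

The population Q_z is summarised by the plain mean of the subject-level
Q̂_iz. The interval is a t-interval on n−1 degrees of freedom over the
subject estimates — the simplest interval consistent with "mean with its
CI"; the level is a parameter (default 0.95). The instrument passes when
the interval's lower bound exceeds δ, the minimum acceptable probability
of revealing the disease status (default 0.5 = pure chance; the
comparison is one-sided by design, since only "better than δ" is of
interest). No hierarchical pooling is attempted: the subject estimates
enter with equal weight.

Responsiveness: dichotomizing at a stricter scale z > z′ should raise
the latent threshold, so the per-subject shifts â_iz − â_iz′ are tested
one-sided for positive location with the Wilcoxon signed-rank test. The
shift distribution is typically skewed, so the median is the headline
statistic. Zero differences are dropped (classical Wilcoxon convention;
Pratt's zero-ranking method is available behind a flag). With ≤ 20
nonzero differences the null distribution is enumerated exactly by
dynamic programming over doubled midranks — handling ties, which closed
forms do not — otherwise the normal approximation with tie correction is
used. If every difference is zero the test statistic is undefined; the
responsiveness table then reports p = 1 with an explicit "degenerate"
label rather than erroring, since the scientific conclusion (no evidence
of responsiveness) is unambiguous.

## Simulation design

The generator reproduces the reference operating-characteristics study.
One subject's t objective outcomes are multivariate normal with mean
block (0, 0.5, 1, 1.5, 2) and variance block (1, 1.3, 1.6, 1.9, 2.2)
cycled to length t (truncating when t is not a multiple of 5), and a
single cross-visit correlation ρ applied to every pair: cov(l, s) =
ρσ_lσ_s. That compound structure is not positive definite for all (ρ, t)
— any ρ < −1/(t−1) fails — so definiteness is verified by Cholesky at
construction. Given x, each g_k is Bernoulli: probability q_true of the
value 1 when x_k ≥ a_true, probability q_true of the value 0 otherwise.
Defaults are the reference study's conditions: ρ ∈ {0.3, 0.5, 0.8},
a_true ∈ {−0.3, 0.4, 1.2}, Q ∈ {0.5..0.9}, t ∈ {5, 10, 20, 40}, grid
−2..5 in steps of 0.1 (m = 71, wide enough to cover all true thresholds
at ±2 SD of the means), 10,000 replicates.

Reproducibility: a master `SeedSequence` spawns one independent child
stream per fixed-size chunk of 2,048 replicates, and the whole chunk is
drawn vectorised from its stream. Results are therefore a bit-exact
function of (seed, config); the batch estimator is verified row-by-row
against the scalar estimator in the tests. The Monte-Carlo standard
error of the mean estimate is reported so scaled-down runs (the `--reps`
flag) can set honest tolerances.

What the generator does **not** emulate: non-normal objective outcomes,
visit-specific dropout or missingness, between-subject heterogeneity in
(Q, a) within one run, or ordinal PRO noise beyond the single
dichotomized Bernoulli response. Passing tests therefore demonstrate the
estimator's behaviour under the stated correlated-normal model, not
robustness to real-world messiness.

Known operating characteristics worth remembering when reading output:
the max rule is biased upward for small t (a maximum of noisy accuracies),
most visibly at Q = 0.5; CI coverage under no association falls below
nominal for large t for the same reason — the package reports this
honestly rather than correcting it. The threshold estimate â converges
more slowly than Q̂ and retains a small upward mean bias at t = 40; its
median across subjects is the better-behaved summary.

## Design choices in the I/O layer

Long-format CSV (subject_id, visit, x, and g or pro) with visits ordered
by the visit column, not file order — the statistics are order-invariant
but reports should be stable. Duplicate (subject, visit) rows are a hard
error (the model assumes one pair per visit). Rows missing x or the
response are dropped with a logged count, and logged subject counts
reconcile (read = eligible + filtered). The pipeline emits per-subject
estimate tables, a population summary per cutoff, and responsiveness
tables for consecutive cutoff pairs plus the extreme pair; everything is
a pure function of (input file, config, seed). CLI exit codes: 0 success,
1 validation error, 2 unexpected error.

## Limitations

- Unidimensional PROMs only; one item of a multi-dimensional instrument
  can be analysed in isolation.
- The threshold grid must be pre-specified; adapting it to the observed
  x range would invalidate the fixed-grid reasoning behind consistency.
- Small t (common in trials, e.g. ≤ 6 visits) limits both the precision
  of â and the bias of Q̂; the minimum acceptable δ should be set with
  the simulated small-t bias in mind (the Q = 0.5 rows of the
  convergence table are the natural reference).
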