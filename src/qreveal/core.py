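"""Revealing-truth probability Q for PROM validation.

A patient-reported outcome measure (PROM) is an ordinal questionnaire a
patient answers at each clinical visit; an objective endpoint X is a
continuous clinical measurement of the same disease status (e.g. change in
hemoglobin count, or change in uncorrected near visual acuity letters).
This module estimates, per subject, the conditional probability Q that the
dichotomized PRO agrees with the side of the subject's latent objective
threshold a on which X falls -- "reveals the truth" -- from t repeated
paired observations (x_k, g_k).

The estimator scans a fixed, pre-specified grid of candidate thresholds
{a_j}: at each grid point the t pairs are cross-classified into a 2x2 table
(x >= a_j vs. g = 1) and the agreement accuracy R_j = (TP + TN) / t is
recorded.  The maximum of R_j over the grid is a consistent estimator of Q
when Q > 0.5, and the median of the grid points attaining the maximum
estimates the latent threshold a.  Under no association (Q = 0.5) every
R_j is unbiased and the median of the R_j is used instead.

Contents, in the order the method runs:

1.  Domain types -- ``PairedSeries``, ``ThresholdGrid``,
    ``ContingencyCounts``, ``ThresholdScan``, ``QEstimate``.
2.  Per-subject estimation -- ``dichotomize``, ``tabulate``, ``scan``,
    ``estimate_q``, ``exact_binomial_ci``, ``variance_estimate``.
3.  Multi-subject inference -- ``aggregate_q`` (mean Q with t-interval and
    a minimum-acceptable-probability test), ``threshold_change`` and
    ``signed_rank_test`` (responsiveness across dichotomizations).
4.  Simulation study -- correlated multivariate-normal objective outcomes
    with conditional Bernoulli PRO responses, Monte-Carlo operating
    characteristics, and a synthetic-fixture writer.
5.  I/O and pipeline -- long-format CSV ingestion, study configuration,
    and the end-to-end report pipeline behind the CLI.
"""

from __future__ import annotations

import json
import logging
import math
import numbers
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "ValidationError",
    "SchemaError",
    "PairedSeries",
    "ThresholdGrid",
    "ContingencyCounts",
    "ThresholdScan",
    "QEstimate",
    "dichotomize",
    "tabulate",
    "scan",
    "estimate_q",
    "estimate_subject",
    "exact_binomial_ci",
    "variance_estimate",
    "PopulationQSummary",
    "ThresholdChangeSummary",
    "is_eligible",
    "aggregate_q",
    "threshold_change",
    "signed_rank_test",
    "SimConfig",
    "SimStudyResult",
    "build_covariance",
    "draw_subject",
    "run_study",
    "convergence_table",
    "write_fixture",
    "StudyConfig",
    "read_long_csv",
    "run_pipeline",
]

logger = logging.getLogger("qreveal")

#: Replicates per RNG chunk in the vectorised Monte-Carlo loop.  Fixed so
#: that results depend only on (seed, config), never on memory layout.
_CHUNK = 2048

Rule = Literal["max", "median"]


class ValidationError(ValueError):
    """Invalid data or parameters (exit code 1 at the CLI)."""


class SchemaError(ValidationError):
    """Input table does not have the required columns."""


# ---------------------------------------------------------------------------
# 1. Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairedSeries:
    """One subject's t repeated paired observations (x_k, g_k).

    Parameters
    ----------
    subject_id : str
        Opaque subject label.
    x : array-like of float
        Continuous objective outcome per visit, in original measurement
        units, ordered by visit.
    g : array-like of {0, 1}
        Dichotomized PRO per visit, same order.
    scale_label : str, optional
        The dichotomization that produced ``g`` (e.g. ``"PRO>=5"``).
    """

    subject_id: str
    x: np.ndarray
    g: np.ndarray
    scale_label: str = ""

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        g = np.asarray(self.g)
        if x.ndim != 1 or g.ndim != 1 or len(x) != len(g):
            raise ValidationError(
                f"subject {self.subject_id!r}: x and g must be 1-d sequences "
                f"of equal length (got {x.shape} and {g.shape})"
            )
        if len(x) < 1:
            raise ValidationError(f"subject {self.subject_id!r}: needs at least one visit")
        if not np.all(np.isfinite(x)):
            raise ValidationError(f"subject {self.subject_id!r}: non-finite objective outcome")
        if not np.isin(g, (0, 1)).all():
            raise ValidationError(f"subject {self.subject_id!r}: g values must be 0 or 1")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "g", g.astype(np.int8))

    @property
    def t(self) -> int:
        """Number of visits."""
        return len(self.x)


@dataclass(frozen=True)
class ThresholdGrid:
    """Fixed, pre-selected searching set {a_j, j = 1..m}.

    The grid spans the clinically plausible range of the objective
    endpoint (e.g. the normal range of human hemoglobin) and is chosen
    before seeing the data; it is never adapted to the observed x values.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or len(pts) < 1:
            raise ValidationError("grid must contain at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("grid points must be finite")
        if len(pts) > 1 and not np.all(np.diff(pts) > 0):
            raise ValidationError("grid points must be strictly increasing")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "ThresholdGrid":
        """Build a grid start, start+step, ... by integer index.

        Generating each point as ``start + j*step`` avoids cumulative
        floating-point drift; the last point is included iff it lands
        within half a step of ``stop``.
        """
        if step <= 0:
            raise ValidationError("grid step must be positive")
        if stop < start:
            raise ValidationError("grid stop must be >= start")
        n_last = int(math.floor((stop - start) / step + 0.5))
        return cls(start + np.arange(n_last + 1) * step)


@dataclass(frozen=True)
class ContingencyCounts:
    """2x2 cell counts at one grid point: rows x >= a / x < a, columns g."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, numbers.Integral) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ThresholdScan:
    """Per-grid-point 2x2 counts and agreement accuracies for one subject.

    ``r[j] = (tp + tn)_j / t`` is the accuracy of classifying the visits
    by the rule x >= a_j against the dichotomized PRO.
    """

    grid: ThresholdGrid
    counts: tuple[ContingencyCounts, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.grid):
            raise ValidationError("one contingency table per grid point required")
        if len(self.counts) == 0:
            raise ValidationError("empty scan")
        t = self.counts[0].total
        for c in self.counts:
            if c.total != t:
                raise ValidationError("all grid points must classify the same t visits")
        r = np.asarray(self.r, dtype=float)
        expect = np.array([(c.tp + c.tn) / t for c in self.counts])
        if r.shape != expect.shape or not np.allclose(r, expect, atol=1e-12):
            raise ValidationError("r must equal (tp+tn)/t at every grid point")
        object.__setattr__(self, "r", r)

    @property
    def t(self) -> int:
        return self.counts[0].total

    @property
    def successes(self) -> np.ndarray:
        """Integer tp+tn per grid point (exact tie comparisons use these)."""
        return np.array([c.tp + c.tn for c in self.counts], dtype=int)


@dataclass(frozen=True)
class QEstimate:
    """Estimate of (Q, a) for one subject at one dichotomization.

    ``q_hat`` is the selected agreement accuracy, ``a_hat`` the estimated
    latent threshold (median of the tied grid points), ``successes`` the
    integer tp+tn behind the binomial variance and exact CI.
    """

    q_hat: float
    a_hat: float
    tie_points: np.ndarray
    successes: int
    n_visits: int
    variance: float
    ci_low: float
    ci_high: float
    rule: Rule
    level: float = 0.95
    subject_id: str = ""
    scale_label: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_hat <= 1.0):
            raise ValidationError("q_hat must lie in [0, 1]")
        if not (self.ci_low - 1e-12 <= self.q_hat <= self.ci_high + 1e-12):
            raise ValidationError("CI must contain the point estimate")
        object.__setattr__(self, "tie_points", np.asarray(self.tie_points, dtype=float))


# ---------------------------------------------------------------------------
# 2. Per-subject estimation
# ---------------------------------------------------------------------------


def dichotomize(pro_scores: Sequence[int], cutoff: int, scale_range: tuple[int, int] = (1, 7)) -> np.ndarray:
    """Dichotomize ordinal PRO scores at a cutoff z: 1 where score >= z.

    Parameters
    ----------
    pro_scores : sequence of int
        Raw ordinal PRO per visit.
    cutoff : int
        Dichotomization scale z; must lie within ``scale_range``.
    scale_range : (int, int)
        Declared range of the PROM instrument (default a 7-point scale).
    """
    lo, hi = scale_range
    if not (lo <= cutoff <= hi):
        raise ValidationError(f"cutoff {cutoff} outside PROM scale range [{lo}, {hi}]")
    out = np.empty(len(pro_scores), dtype=np.int8)
    for k, s in enumerate(pro_scores):
        if not isinstance(s, numbers.Integral) or isinstance(s, bool):
            raise ValidationError(f"visit {k + 1}: PRO score {s!r} is not an integer")
        if not (lo <= s <= hi):
            raise ValidationError(f"visit {k + 1}: PRO score {s} outside scale range [{lo}, {hi}]")
        out[k] = 1 if s >= cutoff else 0
    return out


def tabulate(series: PairedSeries, a: float) -> ContingencyCounts:
    """Cross-classify one subject's visits at a single threshold a.

    A visit is objective-positive when x_k >= a (ties count as positive)
    and PRO-positive when g_k = 1; tp/fp/fn/tn are the four cell counts.
    """
    pos = series.x >= a
    g = series.g.astype(bool)
    return ContingencyCounts(
        tp=int(np.sum(pos & g)),
        fp=int(np.sum(pos & ~g)),
        fn=int(np.sum(~pos & g)),
        tn=int(np.sum(~pos & ~g)),
    )


def scan(series: PairedSeries, grid: ThresholdGrid) -> ThresholdScan:
    """Scan the threshold grid: one 2x2 table and accuracy R_j per point."""
    counts = tuple(tabulate(series, a) for a in grid.points)
    r = np.array([(c.tp + c.tn) / series.t for c in counts])
    return ThresholdScan(grid=grid, counts=counts, r=r)


def exact_binomial_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial confidence interval.

    Inverts the binomial tail sums via beta quantiles; the lower bound is
    0 when successes = 0 and the upper bound is 1 when successes = n.
    """
    if not (0 <= successes <= n) or n < 1:
        raise ValidationError(f"need 0 <= successes <= n, n >= 1; got ({successes}, {n})")
    if not (0.0 < level < 1.0):
        raise ValidationError(f"confidence level must be in (0, 1), got {level}")
    alpha = 1.0 - level
    low = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    high = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return low, high


def variance_estimate(q_hat: float, t: int) -> float:
    """Binomial variance estimate q(1-q)/t of the per-subject Q estimate."""
    if not (0.0 <= q_hat <= 1.0) or t < 1:
        raise ValidationError("need 0 <= q_hat <= 1 and t >= 1")
    return q_hat * (1.0 - q_hat) / t


def _tie_median(points: np.ndarray) -> float:
    # median of tied grid points; for an even count, mean of the middle two
    return float(np.median(points))


def estimate_q(
    scan_result: ThresholdScan,
    rule: Rule = "max",
    level: float = 0.95,
    subject_id: str = "",
    scale_label: str = "",
) -> QEstimate:
    """Estimate (Q, a) from a threshold scan.

    rule="max"
        Q̂ is the maximum of the accuracies R_j -- consistent for Q > 0.5;
        the latent threshold a is estimated by the median of the grid
        points tied at the maximum.
    rule="median"
        Q̂ is the median of the R_j, appropriate under no association
        (Q = 0.5) where every R_j is unbiased.  The reported a_hat (median
        of the grid points whose accuracy is nearest the median) is not
        identified in this regime and is provided for symmetry only.

    Tie detection compares integer tp+tn counts, never floating R values.
    The exact binomial CI and the q(1-q)/t variance are attached; under
    the median rule the binomial success count is ``round(q_hat * t)``, an
    explicit approximation (the binomial argument is exact only at the
    true threshold).
    """
    succ = scan_result.successes
    t = scan_result.t
    grid_pts = scan_result.grid.points

    if rule == "max":
        best = int(succ.max())
        tie_mask = succ == best
        q_hat = best / t
        n_success = best
    elif rule == "median":
        q_hat = float(np.median(succ)) / t
        # nearest achieved count to the median; prefer the smaller count on
        # an exact tie (a_hat is non-identified here, the choice is nominal)
        gap = np.abs(succ - q_hat * t)
        chosen = int(succ[gap <= gap.min() + 1e-9].min())
        tie_mask = succ == chosen
        n_success = int(math.floor(q_hat * t + 0.5))
    else:
        raise ValidationError(f"unknown rule {rule!r}; expected 'max' or 'median'")

    tie_points = grid_pts[tie_mask]
    a_hat = _tie_median(tie_points)
    ci_low, ci_high = exact_binomial_ci(n_success, t, level)
    return QEstimate(
        q_hat=q_hat,
        a_hat=a_hat,
        tie_points=tie_points,
        successes=n_success,
        n_visits=t,
        variance=variance_estimate(q_hat, t),
        ci_low=min(ci_low, q_hat),
        ci_high=max(ci_high, q_hat),
        rule=rule,
        level=level,
        subject_id=subject_id,
        scale_label=scale_label,
    )


def estimate_subject(
    series: PairedSeries, grid: ThresholdGrid, rule: Rule = "max", level: float = 0.95
) -> QEstimate:
    """Convenience wrapper: scan a subject's series and estimate (Q, a).

    Subjects with all-identical objective outcomes or an all-0/all-1 PRO
    column are still estimable but carry little information about the
    threshold; a degenerate-data warning is logged.
    """
    if np.unique(series.x).size < 2 or np.unique(series.g).size < 2:
        logger.warning(
            "subject %s (%s): degenerate data (constant x or constant g); "
            "the threshold estimate is weakly identified",
            series.subject_id,
            series.scale_label or "unlabelled",
        )
    return estimate_q(
        scan(series, grid),
        rule=rule,
        level=level,
        subject_id=series.subject_id,
        scale_label=series.scale_label,
    )


# Vectorised counterparts used by the Monte-Carlo study.  They reproduce
# estimate_q(rule=...) row by row (verified in the test suite) but operate
# on a whole batch of replicates at once.


def _batch_tptn(X: np.ndarray, G: np.ndarray, grid_pts: np.ndarray) -> np.ndarray:
    """tp+tn counts, shape (reps, m), for replicate rows of (X, G)."""
    pos = X[:, :, None] >= grid_pts[None, None, :]
    g = G.astype(bool)[:, :, None]
    return (pos & g).sum(axis=1) + (~pos & ~g).sum(axis=1)


def _batch_tie_median(mask: np.ndarray, grid_pts: np.ndarray) -> np.ndarray:
    """Row-wise median of grid points selected by a boolean mask (reps, m)."""
    c = np.cumsum(mask, axis=1)
    k = c[:, -1]
    if np.any(k == 0):
        raise ValidationError("tie mask selected no grid points")
    lo_rank = (k - 1) // 2 + 1  # 1-based order statistics of the tie set
    hi_rank = k // 2 + 1
    lo_idx = np.argmax(c >= lo_rank[:, None], axis=1)
    hi_idx = np.argmax(c >= hi_rank[:, None], axis=1)
    return 0.5 * (grid_pts[lo_idx] + grid_pts[hi_idx])


def _batch_estimate(
    X: np.ndarray, G: np.ndarray, grid_pts: np.ndarray, rule: Rule
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-replicate (q_hat, a_hat, successes) for a batch of series."""
    t = X.shape[1]
    tptn = _batch_tptn(X, G, grid_pts)
    if rule == "max":
        best = tptn.max(axis=1)
        q_hat = best / t
        a_hat = _batch_tie_median(tptn == best[:, None], grid_pts)
        n_success = best
    elif rule == "median":
        med = np.median(tptn, axis=1)
        q_hat = med / t
        gap = np.abs(tptn - med[:, None])
        min_gap = gap.min(axis=1)
        near = gap <= min_gap[:, None] + 1e-9
        chosen = np.where(near, tptn, np.iinfo(np.int64).max).min(axis=1)
        a_hat = _batch_tie_median(tptn == chosen[:, None], grid_pts)
        n_success = np.floor(q_hat * t + 0.5).astype(int)
    else:
        raise ValidationError(f"unknown rule {rule!r}")
    return q_hat, a_hat, n_success


# ---------------------------------------------------------------------------
# 3. Multi-subject inference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationQSummary:
    """Population-level summary of per-subject Q estimates.

    ``passes`` records whether the CI lower bound exceeds ``delta``, the
    minimum acceptable probability of revealing the disease status.
    """

    n_subjects: int
    mean_q: float
    ci_low: float
    ci_high: float
    level: float
    delta: float
    passes: bool


@dataclass(frozen=True)
class ThresholdChangeSummary:
    """Per-subject threshold shifts between two dichotomizations.

    ``diffs`` holds a_hat(stricter cutoff) - a_hat(looser cutoff) per
    subject; a positive location (tested one-sided by signed rank) means
    the stricter PRO level maps to a genuinely larger objective change,
    i.e. the PROM is responsive to change in the objective endpoint.
    """

    n_subjects: int
    diffs: np.ndarray
    mean_diff: float
    median_diff: float
    p_value: float
    test_name: str


def is_eligible(series: PairedSeries) -> bool:
    """Eligibility filter for population summaries.

    A subject contributes when the dichotomized PRO actually reaches the
    cutoff at least once (some g = 1) and the objective outcomes take at
    least two distinct values, so a threshold is identifiable at all.
    """
    return bool(np.any(series.g == 1)) and np.unique(series.x).size >= 2


def aggregate_q(
    estimates: Sequence[QEstimate], level: float = 0.95, delta: float = 0.5
) -> PopulationQSummary:
    """Mean of per-subject Q estimates with a t-interval and a delta test.

    The population revealing-truth probability is summarised by the plain
    mean of the subject-level estimates with a t-distribution confidence
    interval on n-1 degrees of freedom.  The PROM is declared able to
    reveal disease status (``passes``) when the interval's lower bound
    exceeds ``delta``.
    """
    n = len(estimates)
    if n < 2:
        raise ValidationError("population summary needs at least 2 subjects")
    labels = {e.scale_label for e in estimates if e.scale_label}
    if len(labels) > 1:
        raise ValidationError(f"estimates mix dichotomizations: {sorted(labels)}")
    q = np.array([e.q_hat for e in estimates])
    mean_q = float(q.mean())
    sd = float(q.std(ddof=1))
    half = float(stats.t.ppf((1 + level) / 2, n - 1)) * sd / math.sqrt(n)
    return PopulationQSummary(
        n_subjects=n,
        mean_q=mean_q,
        ci_low=mean_q - half,
        ci_high=mean_q + half,
        level=level,
        delta=delta,
        passes=bool(mean_q - half > delta),
    )


def _exact_signed_rank_sf(diffs: np.ndarray, w_plus: float) -> tuple[float, float]:
    """Exact P(W+ >= w) and P(W+ <= w) by dynamic programming.

    Under the null, each |difference| keeps its (mid)rank and receives an
    independent random sign.  Midranks can be half-integers, so ranks are
    doubled to integers and the distribution of the doubled positive-rank
    sum is built by convolution.
    """
    ranks = stats.rankdata(np.abs(diffs))
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for rr in r2:
        new = dist.copy()
        new[rr:] += dist[: total + 1 - rr]
        dist = new
    dist /= dist.sum()
    w2 = int(round(2 * w_plus))
    return float(dist[w2:].sum()), float(dist[: w2 + 1].sum())


def signed_rank_test(
    diffs: Sequence[float],
    alternative: Literal["greater", "two-sided"] = "greater",
    zero_method: Literal["wilcox", "pratt"] = "wilcox",
    exact_limit: int = 20,
) -> float:
    """Wilcoxon signed-rank p-value for the location of paired differences.

    Zero differences are dropped (classical Wilcoxon convention; Pratt's
    method, which ranks zeros then discards them, is available via
    ``zero_method="pratt"``).  With at most ``exact_limit`` nonzero
    differences the null distribution is enumerated exactly (midranks for
    tied magnitudes); larger samples use the normal approximation with
    tie correction.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0 or np.all(d == 0):
        raise ValidationError("signed-rank test undefined: all differences are zero")
    if alternative not in ("greater", "two-sided"):
        raise ValidationError(f"unknown alternative {alternative!r}")

    if zero_method == "pratt":
        res = stats.wilcoxon(d, zero_method="pratt", alternative=alternative, method="approx")
        return float(res.pvalue)

    dz = d[d != 0]
    n = dz.size
    if n <= exact_limit:
        ranks = stats.rankdata(np.abs(dz))
        w_plus = float(ranks[dz > 0].sum())
        p_ge, p_le = _exact_signed_rank_sf(dz, w_plus)
        if alternative == "greater":
            return p_ge
        return min(1.0, 2.0 * min(p_ge, p_le))
    res = stats.wilcoxon(dz, zero_method="wilcox", alternative=alternative, method="approx")
    return float(res.pvalue)


def threshold_change(
    est_strict: Sequence[QEstimate], est_loose: Sequence[QEstimate]
) -> ThresholdChangeSummary:
    """Per-subject threshold shift between two dichotomizations.

    ``est_strict`` holds estimates at the stricter (higher) cutoff z,
    ``est_loose`` at the looser cutoff z'.  Subjects are paired by id;
    diffs are a_hat(z) - a_hat(z').  Because the shift distribution is
    typically skewed, the headline statistic is the median and the test
    is the one-sided signed-rank test of location > 0.
    """
    strict_by_id = {e.subject_id: e for e in est_strict}
    loose_by_id = {e.subject_id: e for e in est_loose}
    if len(strict_by_id) != len(est_strict) or len(loose_by_id) != len(est_loose):
        raise ValidationError("duplicate subject ids within one cutoff's estimates")
    only_strict = sorted(set(strict_by_id) - set(loose_by_id))
    only_loose = sorted(set(loose_by_id) - set(strict_by_id))
    if only_strict or only_loose:
        raise ValidationError(
            "estimates are not paired by subject: "
            f"missing at looser cutoff {only_strict}, missing at stricter cutoff {only_loose}"
        )
    ids = sorted(strict_by_id)
    diffs = np.array([strict_by_id[i].a_hat - loose_by_id[i].a_hat for i in ids])
    if np.all(diffs == 0):
        # no shift anywhere: the signed-rank statistic is undefined, but the
        # scientific answer is unambiguous -- no evidence of responsiveness
        p = 1.0
        test_name = "signed-rank (degenerate: all differences zero)"
    else:
        p = signed_rank_test(diffs, alternative="greater")
        test_name = "one-sided Wilcoxon signed-rank"
    return ThresholdChangeSummary(
        n_subjects=len(ids),
        diffs=diffs,
        mean_diff=float(diffs.mean()),
        median_diff=float(np.median(diffs)),
        p_value=p,
        test_name=test_name,
    )


# ---------------------------------------------------------------------------
# 4. Simulation study
# ---------------------------------------------------------------------------

_DEFAULT_MU_BLOCK = (0.0, 0.5, 1.0, 1.5, 2.0)
_DEFAULT_VAR_BLOCK = (1.0, 1.3, 1.6, 1.9, 2.2)


def _default_grid() -> ThresholdGrid:
    return ThresholdGrid.from_range(-2.0, 5.0, 0.1)


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one Monte-Carlo cell.

    The objective outcomes of one subject's t visits are multivariate
    normal with mean and variance blocks cycled to length t and a single
    cross-visit correlation rho (off-diagonal covariance rho*sigma_l*
    sigma_s).  Given x_k, the dichotomized PRO g_k is Bernoulli(q_true)
    for the value 1 when x_k >= a_true and Bernoulli(q_true) for the
    value 0 otherwise.
    """

    rho: float
    a_true: float
    q_true: float
    t: int
    mu_block: tuple[float, ...] = _DEFAULT_MU_BLOCK
    var_block: tuple[float, ...] = _DEFAULT_VAR_BLOCK
    grid: ThresholdGrid = field(default_factory=_default_grid)
    n_reps: int = 10_000
    seed: int = 0
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not (-1.0 < self.rho < 1.0):
            raise ValidationError(f"rho must be in (-1, 1), got {self.rho}")
        if not (0.0 <= self.q_true <= 1.0):
            raise ValidationError(f"q_true must be in [0, 1], got {self.q_true}")
        if not isinstance(self.t, numbers.Integral) or self.t < 1:
            raise ValidationError(f"t must be a positive integer, got {self.t!r}")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be positive")
        if len(self.mu_block) != len(self.var_block) or len(self.mu_block) == 0:
            raise ValidationError("mean and variance blocks must have equal, nonzero length")
        if any(v <= 0 for v in self.var_block):
            raise ValidationError("variances must be positive")
        build_covariance(self)  # positive definiteness checked at construction

    @property
    def mean_vector(self) -> np.ndarray:
        """Mean block cycled (and truncated) to length t."""
        block = np.asarray(self.mu_block, dtype=float)
        return np.resize(block, self.t)

    @property
    def variance_vector(self) -> np.ndarray:
        block = np.asarray(self.var_block, dtype=float)
        return np.resize(block, self.t)


@dataclass(frozen=True)
class SimStudyResult:
    """Monte-Carlo summary for one configuration."""

    config: SimConfig
    rule: Rule
    mean_q_hat: float
    coverage: float
    mean_a_hat: float
    mc_se: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage <= 1.0):
            raise ValidationError("coverage must lie in [0, 1]")


def build_covariance(config: SimConfig) -> np.ndarray:
    """t x t covariance: cycled variances on the diagonal, rho*s_l*s_s off it.

    A single correlation applied to every visit pair is not positive
    definite for all (rho, t) -- e.g. any rho < -1/(t-1) fails -- so
    definiteness is verified numerically via a Cholesky factorization.
    """
    sd = np.sqrt(config.variance_vector)
    cov = config.rho * np.outer(sd, sd)
    np.fill_diagonal(cov, config.variance_vector)
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        raise ValidationError(
            f"covariance matrix is not positive definite for rho={config.rho}, t={config.t}"
        ) from None
    return cov


def _draw_batch(
    config: SimConfig, rng: np.random.Generator, n: int, chol: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n replicate subjects at once: X (n, t) and G (n, t)."""
    z = rng.standard_normal((n, config.t))
    x = config.mean_vector + z @ chol.T
    u = rng.random((n, config.t))
    p_one = np.where(x >= config.a_true, config.q_true, 1.0 - config.q_true)
    g = (u < p_one).astype(np.int8)
    return x, g


def draw_subject(config: SimConfig, rng: np.random.Generator) -> PairedSeries:
    """Draw one subject's paired series under the simulation model.

    x is one draw from the multivariate normal; each g_k is Bernoulli
    with success probability q_true when x_k >= a_true and 1 - q_true
    otherwise (equivalently: probability q_true of landing on the side
    of the truth).
    """
    chol = np.linalg.cholesky(build_covariance(config))
    x, g = _draw_batch(config, rng, 1, chol)
    return PairedSeries(subject_id="sim", x=x[0], g=g[0], scale_label=f"sim q={config.q_true}")


def _cp_table(t: int, level: float) -> tuple[np.ndarray, np.ndarray]:
    """Clopper-Pearson bounds for every success count 0..t."""
    lows = np.empty(t + 1)
    highs = np.empty(t + 1)
    for s in range(t + 1):
        lows[s], highs[s] = exact_binomial_ci(s, t, level)
    return lows, highs


def run_study(config: SimConfig, rule: Rule = "max") -> SimStudyResult:
    """Monte-Carlo operating characteristics of the (Q, a) estimator.

    For each replicate a fresh subject is drawn, (Q, a) is estimated over
    ``config.grid`` with the given rule, and the exact binomial CI is
    checked for coverage of ``q_true``.  Replicates are generated in
    fixed-size chunks, each from its own stream spawned off the master
    seed, so results are bit-reproducible for a given (seed, config) and
    independent of chunking internals.
    """
    chol = np.linalg.cholesky(build_covariance(config))
    grid_pts = config.grid.points
    lows, highs = _cp_table(config.t, config.ci_level)

    n_chunks = -(-config.n_reps // _CHUNK)
    streams = np.random.SeedSequence(config.seed).spawn(n_chunks)
    q_all: list[np.ndarray] = []
    a_all: list[np.ndarray] = []
    covered = 0
    left = config.n_reps
    for ss in streams:
        n = min(_CHUNK, left)
        left -= n
        rng = np.random.default_rng(ss)
        x, g = _draw_batch(config, rng, n, chol)
        q_hat, a_hat, n_success = _batch_estimate(x, g, grid_pts, rule)
        covered += int(np.sum((lows[n_success] <= config.q_true) & (config.q_true <= highs[n_success])))
        q_all.append(q_hat)
        a_all.append(a_hat)
    q = np.concatenate(q_all)
    a = np.concatenate(a_all)
    return SimStudyResult(
        config=config,
        rule=rule,
        mean_q_hat=float(q.mean()),
        coverage=covered / config.n_reps,
        mean_a_hat=float(a.mean()),
        mc_se=float(q.std(ddof=1) / math.sqrt(config.n_reps)),
    )


def convergence_table(
    rho: float,
    a_true: float,
    ts: Sequence[int] = (5, 10, 20, 40),
    q_trues: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9),
    n_reps: int = 10_000,
    rule: Rule = "max",
    seed: int = 0,
    grid: ThresholdGrid | None = None,
) -> pd.DataFrame:
    """Mean Q̂ by (t, q_true): the estimator's convergence pattern.

    One row per number of visits t, one column per true Q.  As t grows
    the mean estimate approaches the true Q for Q > 0.5; the upward bias
    of the max rule is largest at small t and weak association.
    """
    grid = grid or _default_grid()
    rows = {}
    child = np.random.SeedSequence(seed).spawn(len(ts) * len(q_trues))
    k = 0
    for t in ts:
        row = {}
        for q_true in q_trues:
            cfg = SimConfig(
                rho=rho, a_true=a_true, q_true=q_true, t=int(t),
                grid=grid, n_reps=n_reps,
                seed=int(child[k].generate_state(1)[0] % 2**31),
            )
            row[q_true] = run_study(cfg, rule=rule).mean_q_hat
            k += 1
        rows[t] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "t"
    table.columns.name = "q_true"
    return table


def write_fixture(config: SimConfig, n_subjects: int, path: str | Path) -> Path:
    """Write a synthetic long-format CSV of n subjects plus a truth sidecar.

    The CSV has columns subject_id, visit, x, g and is consumable by
    ``read_long_csv``; ``<path>.truth.json`` records a_true and q_true
    per subject for parameter-recovery checks.
    """
    path = Path(path)
    if n_subjects < 1:
        raise ValidationError("n_subjects must be positive")
    streams = np.random.SeedSequence(config.seed).spawn(n_subjects)
    rows = []
    truth: dict[str, dict[str, float]] = {}
    for i, ss in enumerate(streams, start=1):
        sid = f"S{i:04d}"
        series = draw_subject(config, np.random.default_rng(ss))
        for k in range(series.t):
            rows.append((sid, k + 1, series.x[k], int(series.g[k])))
        truth[sid] = {"a_true": config.a_true, "q_true": config.q_true}
    frame = pd.DataFrame(rows, columns=["subject_id", "visit", "x", "g"])
    try:
        frame.to_csv(path, index=False)
        sidecar = path.with_name(path.name + ".truth.json")
        sidecar.write_text(json.dumps(truth, indent=1))
    except OSError as exc:
        raise OSError(f"cannot write fixture to {path}: {exc}") from exc
    return path


# ---------------------------------------------------------------------------
# 5. I/O and pipeline
# ---------------------------------------------------------------------------

_REQUIRED_COLS = {"subject_id", "visit", "x"}


def read_long_csv(path: str | Path, dichotomize_at: int | None = None,
                  scale_range: tuple[int, int] = (1, 7)) -> list[PairedSeries]:
    """Read long-format paired observations into one series per subject.

    The CSV must have a header with columns ``subject_id``, ``visit``,
    ``x`` and either ``g`` (binary) or ``pro`` (ordinal; requires
    ``dichotomize_at``).  Visits are sorted ascending within subject;
    rows with missing x or g/pro are dropped with a logged count, and
    duplicate (subject, visit) rows are an error.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = _REQUIRED_COLS - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    has_g = "g" in df.columns
    has_pro = "pro" in df.columns
    if not has_g and not has_pro:
        raise SchemaError(f"{path}: needs a 'g' (binary) or 'pro' (ordinal) column")
    response_col = "pro" if (has_pro and dichotomize_at is not None) else ("g" if has_g else "pro")
    if response_col == "pro" and dichotomize_at is None:
        raise ValidationError(f"{path}: 'pro' column present but no dichotomization cutoff given")

    n_raw = len(df)
    df = df.dropna(subset=["x", response_col])
    if n_raw - len(df):
        logger.info("%s: dropped %d rows with missing x or %s", path, n_raw - len(df), response_col)
    dup = df.duplicated(subset=["subject_id", "visit"])
    if dup.any():
        pairs = df.loc[dup, ["subject_id", "visit"]].values.tolist()
        raise ValidationError(f"{path}: duplicate (subject, visit) rows: {pairs[:5]}")

    out: list[PairedSeries] = []
    for sid, sub in df.groupby("subject_id", sort=True):
        sub = sub.sort_values("visit")
        x = sub["x"].to_numpy(dtype=float)
        if response_col == "pro":
            scores = sub["pro"].to_numpy()
            if not np.all(scores == np.rint(scores)):
                raise ValidationError(f"subject {sid!r}: non-integer PRO score")
            g = dichotomize([int(s) for s in scores], dichotomize_at, scale_range)
            label = f"PRO>={dichotomize_at}"
        else:
            g = sub["g"].to_numpy()
            if not np.isin(g, (0, 1)).all():
                bad = sub.loc[~np.isin(g, (0, 1)), "visit"].tolist()
                raise ValidationError(f"subject {sid!r}: non-binary g at visits {bad}")
            label = "g"
        out.append(PairedSeries(subject_id=str(sid), x=x, g=g, scale_label=label))
    return out


@dataclass
class StudyConfig:
    """End-to-end pipeline configuration (CLI flags or YAML)."""

    input_path: str
    output_dir: str = "qreveal_out"
    grid_min: float | None = None
    grid_max: float | None = None
    grid_step: float | None = None
    grid_points: Sequence[float] | None = None
    cutoffs: Sequence[int] = (5, 6, 7)
    ci_level: float = 0.95
    delta: float = 0.5
    rule: Rule = "max"
    eligibility_filter: bool = True
    scale_range: tuple[int, int] = (1, 7)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.ci_level < 1.0):
            raise ValidationError("ci_level must be in (0, 1)")
        lo, hi = self.scale_range
        cut = list(self.cutoffs)
        if cut != sorted(set(cut)) or any(not (lo <= c <= hi) for c in cut):
            raise ValidationError(
                f"cutoffs must be strictly increasing within the scale range [{lo}, {hi}]"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, Mapping):
            raise ValidationError(f"{path}: YAML config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = dict(raw)
        if "cutoffs" in cfg:
            cfg["cutoffs"] = tuple(int(c) for c in cfg["cutoffs"])
        if "scale_range" in cfg:
            cfg["scale_range"] = tuple(cfg["scale_range"])
        return cls(**cfg)

    def build_grid(self) -> ThresholdGrid:
        if self.grid_points is not None:
            return ThresholdGrid(np.asarray(list(self.grid_points), dtype=float))
        if None in (self.grid_min, self.grid_max, self.grid_step):
            raise ValidationError("grid requires either explicit points or (min, max, step)")
        return ThresholdGrid.from_range(self.grid_min, self.grid_max, self.grid_step)


def _estimates_frame(estimates: Sequence[QEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [e.subject_id for e in estimates],
            "q_hat": [e.q_hat for e in estimates],
            "a_hat": [e.a_hat for e in estimates],
            "successes": [e.successes for e in estimates],
            "n_visits": [e.n_visits for e in estimates],
            "variance": [e.variance for e in estimates],
            "ci_low": [e.ci_low for e in estimates],
            "ci_high": [e.ci_high for e in estimates],
        }
    )


def run_pipeline(config: StudyConfig) -> dict[str, pd.DataFrame]:
    """Run the full study: per-subject estimates, population summaries,
    and responsiveness tables; write CSV reports to ``output_dir``.

    For every dichotomization cutoff the input is re-dichotomized (when a
    raw ``pro`` column is present), each eligible subject's (Q, a) is
    estimated over the grid, the population mean Q with its t-interval is
    compared against delta, and threshold shifts between consecutive and
    extreme cutoff pairs are tested by signed rank.  Returns the report
    tables keyed by file stem; outputs are a pure function of (input,
    config, seed).
    """
    grid = config.build_grid()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    probe = pd.read_csv(config.input_path, nrows=0)
    has_pro = "pro" in probe.columns
    cutoffs = list(config.cutoffs) if has_pro else [None]

    reports: dict[str, pd.DataFrame] = {}
    estimates_by_cutoff: dict[int | None, list[QEstimate]] = {}
    pop_rows = []
    for z in cutoffs:
        try:
            series_list = read_long_csv(config.input_path, dichotomize_at=z,
                                        scale_range=config.scale_range)
        except ValidationError as exc:
            raise ValidationError(f"stage read (cutoff {z}): {exc}") from exc
        n_read = len(series_list)
        if config.eligibility_filter:
            eligible = [s for s in series_list if is_eligible(s)]
        else:
            eligible = series_list
        n_filtered = n_read - len(eligible)
        logger.info(
            "cutoff %s: read %d subjects = %d eligible + %d filtered",
            z, n_read, len(eligible), n_filtered,
        )
        if not eligible:
            raise ValidationError(f"stage estimate (cutoff {z}): no eligible subjects")
        ests = [
            estimate_subject(s, grid, rule=config.rule, level=config.ci_level)
            for s in eligible
        ]
        estimates_by_cutoff[z] = ests
        tag = f"z{z}" if z is not None else "g"
        frame = _estimates_frame(ests)
        frame.insert(0, "cutoff", tag)
        reports[f"estimates_{tag}"] = frame
        frame.to_csv(out_dir / f"estimates_{tag}.csv", index=False)

        if len(ests) >= 2:
            summ = aggregate_q(ests, level=config.ci_level, delta=config.delta)
            pop_rows.append(
                {
                    "cutoff": tag,
                    "n_subjects": summ.n_subjects,
                    "mean_q": summ.mean_q,
                    "ci_low": summ.ci_low,
                    "ci_high": summ.ci_high,
                    "level": summ.level,
                    "delta": summ.delta,
                    "passes": summ.passes,
                }
            )
    if pop_rows:
        pop = pd.DataFrame(pop_rows)
        reports["population_summary"] = pop
        pop.to_csv(out_dir / "population_summary.csv", index=False)

    # responsiveness: consecutive cutoff pairs plus the extreme pair
    real_cutoffs = [z for z in cutoffs if z is not None]
    pairs = [(b, a) for a, b in zip(real_cutoffs, real_cutoffs[1:])]
    if len(real_cutoffs) > 2:
        pairs.append((real_cutoffs[-1], real_cutoffs[0]))
    resp_rows = []
    for z_strict, z_loose in pairs:
        strict = {e.subject_id: e for e in estimates_by_cutoff[z_strict]}
        loose = {e.subject_id: e for e in estimates_by_cutoff[z_loose]}
        shared = sorted(set(strict) & set(loose))
        n_excluded = len(set(strict) ^ set(loose))
        if n_excluded:
            logger.info(
                "responsiveness %d vs %d: excluded %d subjects missing an estimate at one cutoff",
                z_strict, z_loose, n_excluded,
            )
        if len(shared) < 2:
            logger.warning("responsiveness %d vs %d: fewer than 2 paired subjects, skipped",
                           z_strict, z_loose)
            continue
        summ = threshold_change([strict[i] for i in shared], [loose[i] for i in shared])
        resp_rows.append(
            {
                "change": f">= {z_loose} to >= {z_strict}",
                "n_subjects": summ.n_subjects,
                "mean_diff": summ.mean_diff,
                "median_diff": summ.median_diff,
                "p_value": summ.p_value,
                "test": summ.test_name,
            }
        )
    if resp_rows:
        resp = pd.DataFrame(resp_rows)
        reports["responsiveness"] = resp
        resp.to_csv(out_dir / "responsiveness.csv", index=False)

    logger.info(
        "pipeline done: grid m=%d [%g..%g], rule=%s, filter=%s, seed=%d",
        len(grid), grid.points[0], grid.points[-1],
        config.rule, config.eligibility_filter, config.seed,
    )
    return reports
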