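"""Per-subject estimation: dichotomization, threshold scan, (Q, a) estimate."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qreveal import (
    PairedSeries,
    ThresholdGrid,
    ValidationError,
    dichotomize,
    estimate_q,
    estimate_subject,
    exact_binomial_ci,
    scan,
    tabulate,
    variance_estimate,
)

from conftest import brute_force_max_estimate


class TestDichotomize:
    @pytest.mark.parametrize(
        "scores, cutoff, expected",
        [
            ((3, 5, 7), 5, (0, 1, 1)),
            ((1, 1, 1), 1, (1, 1, 1)),
            ((7, 6, 5, 4), 7, (1, 0, 0, 0)),
        ],
    )
    def test_threshold_rule(self, scores, cutoff, expected):
        assert tuple(dichotomize(scores, cutoff)) == expected

    def test_out_of_range_score_names_the_visit(self):
        with pytest.raises(ValidationError, match="visit 3"):
            dichotomize((2, 3, 9), 5)

    def test_non_integer_score_rejected(self):
        with pytest.raises(ValidationError, match="visit 2"):
            dichotomize((2, 3.5, 4), 3)

    def test_cutoff_outside_scale_rejected(self):
        with pytest.raises(ValidationError, match="cutoff"):
            dichotomize((1, 2, 3), 9)


# Full per-grid-point 2x2 tables for the two toy series (tp, tn, fp, fn).
TOY_TABLE_FIRST = {
    5.0: (6, 0, 3, 0), 6.0: (6, 1, 2, 0), 8.0: (6, 2, 1, 0),
    10.0: (6, 3, 0, 0), 11.0: (6, 3, 0, 0), 12.0: (5, 3, 0, 1),
    13.5: (3, 3, 0, 3), 15.0: (2, 3, 0, 4), 16.0: (1, 3, 0, 5),
}
TOY_TABLE_SECOND = {
    5.0: (7, 0, 2, 0), 6.0: (7, 1, 1, 0), 8.0: (6, 1, 1, 1),
    10.0: (6, 2, 0, 1), 11.0: (6, 2, 0, 1), 12.0: (5, 2, 0, 2),
    13.5: (3, 2, 0, 4), 15.0: (2, 2, 0, 5), 16.0: (1, 2, 0, 6),
}


class TestTabulate:
    @pytest.mark.parametrize("a", sorted(TOY_TABLE_FIRST))
    def test_toy_first_sample_tables(self, toy_first, a):
        c = tabulate(toy_first, a)
        assert (c.tp, c.tn, c.fp, c.fn) == TOY_TABLE_FIRST[a]

    @pytest.mark.parametrize("a", sorted(TOY_TABLE_SECOND))
    def test_toy_second_sample_tables(self, toy_second, a):
        c = tabulate(toy_second, a)
        assert (c.tp, c.tn, c.fp, c.fn) == TOY_TABLE_SECOND[a]

    def test_tie_x_equal_a_counts_positive(self):
        s = PairedSeries("s", [2.0, 2.0, 3.0], [1, 0, 1])
        c = tabulate(s, 2.0)
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 0, 0)

    def test_all_true_negative(self):
        s = PairedSeries("s", [0.0, 1.0, 2.0], [0, 0, 0])
        c = tabulate(s, 5.0)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 0, 3)


@st.composite
def random_series_and_grid(draw):
    t = draw(st.integers(1, 8))
    x = draw(st.lists(st.integers(-20, 20).map(lambda v: v / 2), min_size=t, max_size=t))
    g = draw(st.lists(st.integers(0, 1), min_size=t, max_size=t))
    m = draw(st.integers(1, 12))
    pts = draw(
        st.lists(st.integers(-25, 25).map(lambda v: v / 2), min_size=m, max_size=m, unique=True)
    )
    return PairedSeries("h", np.array(x), np.array(g)), ThresholdGrid(np.sort(pts))


class TestScan:
    def test_toy_r_columns(self, toy_first, toy_second, toy_grid):
        r1 = np.round(scan(toy_first, toy_grid).r, 2)
        r2 = np.round(scan(toy_second, toy_grid).r, 2)
        assert tuple(r1) == (0.67, 0.78, 0.89, 1.00, 1.00, 0.89, 0.67, 0.56, 0.44)
        assert tuple(r2) == (0.78, 0.89, 0.78, 0.89, 0.89, 0.78, 0.56, 0.44, 0.33)

    def test_single_point_grid(self, toy_first):
        sc = scan(toy_first, ThresholdGrid(np.array([10.0])))
        c = tabulate(toy_first, 10.0)
        assert len(sc.counts) == 1
        assert sc.r[0] == (c.tp + c.tn) / toy_first.t

    def test_matches_direct_recount(self):
        rng = np.random.default_rng(20240917)
        for _ in range(25):
            t = 6
            s = PairedSeries("r", rng.normal(size=t), rng.integers(0, 2, size=t))
            grid = ThresholdGrid(np.sort(rng.choice(np.arange(-30, 30) / 10, 20, replace=False)))
            sc = scan(s, grid)
            for j, a in enumerate(grid.points):
                agree = sum(int((xk >= a) == bool(gk)) for xk, gk in zip(s.x, s.g))
                assert sc.counts[j].tp + sc.counts[j].tn == agree
                assert sc.counts[j].total == t

    @settings(max_examples=200, derandomize=True)
    @given(random_series_and_grid())
    def test_conservation_and_monotone_margins(self, sg):
        series, grid = sg
        sc = scan(series, grid)
        pos = np.array([c.tp + c.fp for c in sc.counts])
        neg = np.array([c.fn + c.tn for c in sc.counts])
        assert all(c.total == series.t for c in sc.counts)
        assert np.all(np.diff(pos) <= 0)  # raising the threshold can only lose positives
        assert np.all(np.diff(neg) >= 0)
        assert np.all((0 <= sc.r) & (sc.r <= 1))


class TestEstimateQ:
    def test_toy_first_sample(self, toy_first, toy_grid):
        est = estimate_q(scan(toy_first, toy_grid))
        assert est.q_hat == 1.0
        assert est.a_hat == 10.5  # even tie {10, 11} -> mean of the middle two
        assert tuple(est.tie_points) == (10.0, 11.0)
        assert est.successes == 9 and est.n_visits == 9

    def test_toy_second_sample(self, toy_second, toy_grid):
        est = estimate_q(scan(toy_second, toy_grid))
        assert round(est.q_hat, 2) == 0.89
        assert est.a_hat == 10.0  # odd tie {6, 10, 11} -> middle point
        assert tuple(est.tie_points) == (6.0, 10.0, 11.0)
        assert est.successes == 8

    def test_perfect_separation_recovers_threshold(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        c = 2.5
        s = PairedSeries("p", x, (x >= c).astype(int))
        grid = ThresholdGrid.from_range(0.0, 5.0, 0.5)
        est = estimate_q(scan(s, grid))
        assert est.q_hat == 1.0
        assert 2.0 < est.a_hat <= 3.0  # within the tie band bracketing c

    def test_max_rule_matches_enumeration_oracle(self):
        rng = np.random.default_rng(55)
        for _ in range(300):
            t = rng.integers(1, 9)
            m = rng.integers(1, 13)
            x = rng.integers(-10, 11, size=t) / 2
            g = rng.integers(0, 2, size=t)
            pts = np.sort(rng.choice(np.arange(-12, 13) / 2, size=m, replace=False))
            est = estimate_q(scan(PairedSeries("o", x, g), ThresholdGrid(pts)))
            q_ref, a_ref, succ_ref = brute_force_max_estimate(x, g, pts)
            assert est.q_hat == pytest.approx(q_ref)
            assert est.a_hat == pytest.approx(a_ref)
            assert est.successes == succ_ref

    def test_rule_ordering_bounds(self, toy_second, toy_grid):
        sc = scan(toy_second, toy_grid)
        q_max = estimate_q(sc, rule="max").q_hat
        q_med = estimate_q(sc, rule="median").q_hat
        assert q_max >= q_med >= sc.r.min()

    @settings(max_examples=150, derandomize=True)
    @given(random_series_and_grid())
    def test_median_rule_flip_symmetry(self, sg):
        """Complementing g complements every accuracy, so the median flips."""
        series, grid = sg
        q = estimate_q(scan(series, grid), rule="median").q_hat
        flipped = PairedSeries(series.subject_id, series.x, 1 - series.g)
        q_flip = estimate_q(scan(flipped, grid), rule="median").q_hat
        assert q_flip == pytest.approx(1.0 - q)

    def test_median_rule_toy_values(self, toy_first, toy_grid):
        est = estimate_q(scan(toy_first, toy_grid), rule="median")
        assert est.q_hat == pytest.approx(7 / 9)  # median of sorted tp+tn counts
        assert est.successes == 7
        assert est.rule == "median"

    def test_unknown_rule_rejected(self, toy_first, toy_grid):
        with pytest.raises(ValidationError, match="rule"):
            estimate_q(scan(toy_first, toy_grid), rule="mean")

    def test_degenerate_series_warns_but_estimates(self, toy_grid, caplog):
        s = PairedSeries("flat", [7.0, 7.0, 7.0], [1, 0, 1])
        with caplog.at_level("WARNING", logger="qreveal"):
            est = estimate_subject(s, toy_grid)
        assert "degenerate" in caplog.text
        assert 0.0 <= est.q_hat <= 1.0


class TestExactBinomialCI:
    def test_boundary_identities(self):
        assert exact_binomial_ci(0, 10)[0] == 0.0
        assert exact_binomial_ci(10, 10)[1] == 1.0

    def test_against_tail_inversion_oracle(self):
        # frozen from numeric root-finding on binomial tail sums
        low, high = exact_binomial_ci(8, 9, 0.95)
        assert low == pytest.approx(0.5175034850826629, abs=1e-9)
        assert high == pytest.approx(0.9971908632534002, abs=1e-9)

    def test_against_statsmodels(self):
        from statsmodels.stats.proportion import proportion_confint

        for s, n in [(1, 5), (3, 7), (20, 40), (39, 40)]:
            low, high = exact_binomial_ci(s, n, 0.95)
            sm_low, sm_high = proportion_confint(s, n, alpha=0.05, method="beta")
            assert low == pytest.approx(sm_low, abs=1e-10)
            assert high == pytest.approx(sm_high, abs=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            exact_binomial_ci(5, 4)
        with pytest.raises(ValidationError):
            exact_binomial_ci(1, 4, level=1.5)


class TestVarianceEstimate:
    @pytest.mark.parametrize(
        "q, t, expected",
        [(0.5, 10, 0.025), (1.0, 9, 0.0), (0.89, 9, 0.0109)],
    )
    def test_binomial_variance(self, q, t, expected):
        assert variance_estimate(q, t) == pytest.approx(expected, abs=5e-5)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            variance_estimate(1.2, 5)


class TestDomainTypes:
    def test_series_validation(self):
        with pytest.raises(ValidationError, match="equal length"):
            PairedSeries("s", [1.0, 2.0], [1])
        with pytest.raises(ValidationError, match="0 or 1"):
            PairedSeries("s", [1.0, 2.0], [1, 2])
        with pytest.raises(ValidationError, match="finite"):
            PairedSeries("s", [1.0, np.nan], [1, 0])

    def test_grid_validation(self):
        with pytest.raises(ValidationError, match="increasing"):
            ThresholdGrid(np.array([1.0, 1.0, 2.0]))
        with pytest.raises(ValidationError, match="at least one"):
            ThresholdGrid(np.array([]))

    def test_grid_from_range_index_generation(self):
        grid = ThresholdGrid.from_range(-2.0, 5.0, 0.1)
        assert len(grid) == 71
        for target in (-0.3, 0.4, 1.2):
            assert np.min(np.abs(grid.points - target)) < 1e-9

    def test_grid_from_range_half_step_inclusion(self):
        assert len(ThresholdGrid.from_range(0.0, 1.0, 0.3)) == 4  # last point 0.9
        assert len(ThresholdGrid.from_range(0.0, 1.05, 0.3)) == 5  # 1.2 within half a step
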