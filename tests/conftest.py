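"""Shared fixtures: the toy worked example and brute-force reference oracles."""

import numpy as np
import pytest

from qreveal import PairedSeries, ThresholdGrid

# Toy worked example: 9 visits of one subject, scanned over a 9-point grid.
# The second series differs from the first only in the response at visit 2.
TOY_X = (5.0, 7.0, 9.0, 11.0, 12.0, 13.0, 14.0, 15.0, 16.0)
TOY_G_FIRST = (0, 0, 0, 1, 1, 1, 1, 1, 1)
TOY_G_SECOND = (0, 1, 0, 1, 1, 1, 1, 1, 1)
TOY_GRID = (5.0, 6.0, 8.0, 10.0, 11.0, 12.0, 13.5, 15.0, 16.0)


@pytest.fixture
def toy_grid() -> ThresholdGrid:
    return ThresholdGrid(np.array(TOY_GRID))


@pytest.fixture
def toy_first() -> PairedSeries:
    return PairedSeries("toy-1", np.array(TOY_X), np.array(TOY_G_FIRST))


@pytest.fixture
def toy_second() -> PairedSeries:
    return PairedSeries("toy-2", np.array(TOY_X), np.array(TOY_G_SECOND))


def brute_force_max_estimate(x, g, grid_points):
    """Reference estimator: exhaustive enumeration of every 2x2 table.

    Independent of the package's scan machinery: recounts agreement at
    each grid point with python loops, takes the maximal count, and takes
    the median of the tied grid points by explicit order statistics.
    """
    x = list(x)
    g = list(g)
    t = len(x)
    agreements = []
    for a in grid_points:
        agree = 0
        for xk, gk in zip(x, g):
            pred = 1 if xk >= a else 0
            agree += int(pred == gk)
        agreements.append(agree)
    best = max(agreements)
    ties = sorted(a for a, s in zip(grid_points, agreements) if s == best)
    n = len(ties)
    if n % 2 == 1:
        a_hat = ties[n // 2]
    else:
        a_hat = 0.5 * (ties[n // 2 - 1] + ties[n // 2])
    return best / t, a_hat, best


def brute_force_signed_rank(diffs, alternative="greater"):
    """Reference signed-rank p-value: enumerate all 2^n sign patterns.

    Magnitudes (and hence midranks) are fixed under the null; every sign
    assignment is equally likely.  Zeros must be removed by the caller.
    """
    from itertools import product

    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    assert np.all(d != 0)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    ws = [sum(r for r, s in zip(ranks, signs) if s) for signs in product((0, 1), repeat=n)]
    total = len(ws)
    p_ge = sum(w >= w_obs - 1e-9 for w in ws) / total
    p_le = sum(w <= w_obs + 1e-9 for w in ws) / total
    if alternative == "greater":
        return p_ge
    return min(1.0, 2.0 * min(p_ge, p_le))
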