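"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's dynamic program: DTW
distances are checked against exhaustive enumeration of every monotone
boundary-complete warp path, and BH q-values against a literal step-up
implementation.
"""

import itertools
import math

import numpy as np
import pytest

from warpscreen import TimeSeries


# ---------------------------------------------------------------- oracles


def enumerate_warp_paths(ta: int, tb: int):
    """Yield every monotone boundary-complete path as 0-based index pairs."""

    def extend(path):
        i, j = path[-1]
        if i == ta - 1 and j == tb - 1:
            yield tuple(path)
            return
        for di, dj in ((1, 1), (1, 0), (0, 1)):
            ni, nj = i + di, j + dj
            if ni < ta and nj < tb:
                yield from extend(path + [(ni, nj)])

    yield from extend([(0, 0)])


def path_cost(a, b, path, step_pattern="fewer_delays", local_distance="absolute"):
    """Cost of one explicit path under the given step pattern (0-based pairs)."""
    cost = 0.0
    prev = None
    for i, j in path:
        d = abs(a[i] - b[j])
        if local_distance == "squared":
            d = d * d
        w = 1.0
        if (
            step_pattern == "symmetric_weighted"
            and prev is not None
            and (i - prev[0], j - prev[1]) == (1, 1)
        ):
            w = 2.0
        cost += w * d
        prev = (i, j)
    return cost


def brute_force_dtw(a, b, step_pattern="fewer_delays", local_distance="absolute"):
    """Minimum cost over exhaustively enumerated paths (lengths <= ~6)."""
    return min(
        path_cost(a, b, path, step_pattern, local_distance)
        for path in enumerate_warp_paths(len(a), len(b))
    )


def stepup_bh(p_values):
    """Literal BH step-up: sort, q_(i) = min_{j>=i} p_(j)*m/j, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def exact_joint_permutation_p(a_values, b_values, dtw_distance_fn):
    """Exact permutation p over all t_a! x t_b! joint orderings.

    Returns the proportion of joint orderings whose distance is <= the
    observed distance (the quantity the add-one estimator converges to,
    up to its (1+K)/(B+1) form).
    """
    a = np.asarray(a_values, float)
    b = np.asarray(b_values, float)
    observed = dtw_distance_fn(a, b)
    hits = total = 0
    for pa in itertools.permutations(range(len(a))):
        for pb in itertools.permutations(range(len(b))):
            total += 1
            hits += dtw_distance_fn(a[list(pa)], b[list(pb)]) <= observed
    return hits / total


def assert_valid_path(path, t_a, t_b):
    """Boundary-complete monotone path contract, checked pair by pair."""
    pairs = path.pairs
    assert pairs[0] == (1, 1)
    assert pairs[-1] == (t_a, t_b)
    for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
        assert (i1 - i0, j1 - j0) in {(1, 0), (0, 1), (1, 1)}


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(20130820)


@pytest.fixture
def series_pair():
    a = TimeSeries("a", [0.0, 0.0, 1.0], [1.0, 2.0, 3.0])
    b = TimeSeries("b", [0.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    return a, b


def random_series(rng, length, label="s"):
    return TimeSeries(label, rng.standard_normal(length), np.arange(length, dtype=float))
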