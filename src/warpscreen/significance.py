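"""Permutation null for DTW distances and BH multiple-testing correction.

A DTW distance alone says nothing about chance: two arbitrary series
always have *some* optimal alignment.  Significance is estimated by
destroying the temporal structure — each permutation draw shuffles the
order of the observed values of the entity and, separately and
independently, of the endpoint, realigns the shuffled pair, and records
the distance.  The p-value uses the add-one estimator

    p = (1 + #{null distances <= observed}) / (B + 1)

which can never be exactly zero (a raw zero would invalidate the
subsequent Benjamini-Hochberg step-up) and counts ties against
significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .dtw import DtwConfig, TimeSeries, dtw_align, dtw_distance_batch


@dataclass(frozen=True)
class PermutationNull:
    """Observed DTW distance with its permutation null distribution."""

    observed_distance: float
    null_distances: np.ndarray
    p_value: float

    def __post_init__(self):
        nd = np.asarray(self.null_distances, dtype=float)
        object.__setattr__(self, "null_distances", nd)
        if np.any(nd < 0):
            raise ValueError("null distances must be non-negative")
        if not 0 < self.p_value <= 1:
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


@dataclass(frozen=True)
class QvalueSet:
    """Raw p-values with their BH step-up adjusted q-values."""

    p_values: np.ndarray
    q_values: np.ndarray
    threshold: float = 0.05

    def significant(self) -> np.ndarray:
        return self.q_values <= self.threshold


def _random_permutations(rng: np.random.Generator, n: int, t: int) -> np.ndarray:
    """n independent uniform permutations of range(t), as an (n, t) index array."""
    return np.argsort(rng.random((n, t)), axis=1)


def permutation_pvalue(
    a: TimeSeries,
    b: TimeSeries,
    n_perm: int = 1000,
    seed: int | np.random.SeedSequence | None = 0,
    dtw_config: DtwConfig = DtwConfig(),
) -> PermutationNull:
    """Empirical p-value for the DTW distance between two scaled series.

    Each of the ``n_perm`` draws permutes the order of ``a``'s values
    and, separately, of ``b``'s values (uniformly over the t! orderings,
    independently per draw and per series), recomputes the DTW distance
    on the permuted pair, and records it.  Reproducible for a given
    ``seed`` (an int or a ``numpy.random.SeedSequence``).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    observed = dtw_align(a, b, dtw_config.step_pattern, dtw_config.local_distance).distance
    rng = np.random.default_rng(seed)
    perm_a = a.values[_random_permutations(rng, n_perm, len(a))]
    perm_b = b.values[_random_permutations(rng, n_perm, len(b))]
    null = dtw_distance_batch(perm_a, perm_b, dtw_config.step_pattern, dtw_config.local_distance)
    p = (1 + int(np.sum(null <= observed))) / (n_perm + 1)
    return PermutationNull(observed_distance=observed, null_distances=null, p_value=p)


def bh_adjust(p_values, threshold: float = 0.05) -> QvalueSet:
    """Benjamini-Hochberg step-up adjusted q-values, in the input order.

    Equivalent to sorting ascending, taking ``q_(i) = min_{j>=i}
    (p_(j) * m / j)`` capped at 1, and mapping back.  An empty input
    yields an empty result; p-values outside (0, 1] are an input error.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be a 1-D vector")
    if p.size == 0:
        return QvalueSet(p_values=p, q_values=p.copy(), threshold=threshold)
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return QvalueSet(p_values=p, q_values=q, threshold=threshold)
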