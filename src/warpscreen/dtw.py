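"""Dynamic time warping between two labelled time courses.

The aligner is a plain dynamic program over monotone, boundary-complete
warp paths: both series must be consumed completely, indices never move
backwards, and each step advances one series, the other, or both.  Two
step patterns are offered:

``fewer_delays``
    the unweighted recursion ``D(i,j) = d(i,j) + min(D(i-1,j), D(i,j-1),
    D(i-1,j-1))``.  Because every visited cell contributes its full local
    cost, longer paths (more inserted delays) accumulate more cost, which
    biases the optimum towards alignments with fewer delays.

``symmetric_weighted``
    the diagonally weighted variant in which a diagonal step costs
    ``2 * d(i,j)`` while horizontal/vertical steps cost ``d(i,j)``, so a
    path's weight budget is independent of how it slants.

The local distance on (already scaled) values is the absolute difference
by default; squared difference is available.  Time-point values are
carried along for plotting but do not enter the alignment cost: warping
operates on index order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

StepPattern = Literal["fewer_delays", "symmetric_weighted"]
LocalDistance = Literal["absolute", "squared"]
ScalingMode = Literal["none", "unit_variance", "mean_center"]

SCALING_MODES = ("none", "unit_variance", "mean_center")
STEP_PATTERNS = ("fewer_delays", "symmetric_weighted")
LOCAL_DISTANCES = ("absolute", "squared")


class DegenerateSeriesError(ValueError):
    """Raised when a zero-variance series cannot be unit-variance scaled."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(
            f"series {label!r} has zero variance and cannot be scaled to "
            f"unit variance; drop it or use a different scaling mode"
        )


@dataclass(frozen=True)
class TimeSeries:
    """One labelled time course.

    Parameters
    ----------
    label
        Text identifier (gene, metabolite, endpoint name ...).
    values
        Measured values, length ``t >= 2``, all finite.
    timepoints
        Strictly increasing numeric time points, same length as ``values``.
        Used for plot axes only; alignment works on index order.
    """

    label: str
    values: np.ndarray
    timepoints: np.ndarray

    def __post_init__(self):
        values = np.asarray(self.values, dtype=float)
        timepoints = np.asarray(self.timepoints, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "timepoints", timepoints)
        if values.ndim != 1 or timepoints.ndim != 1:
            raise ValueError(f"series {self.label!r}: values and timepoints must be 1-D")
        if len(values) != len(timepoints):
            raise ValueError(
                f"series {self.label!r}: {len(values)} values but "
                f"{len(timepoints)} time points"
            )
        if len(values) < 2:
            raise ValueError(f"series {self.label!r}: need at least 2 time points")
        if not np.all(np.isfinite(values)):
            raise ValueError(f"series {self.label!r}: values contain non-finite entries")
        if np.any(np.diff(timepoints) <= 0):
            raise ValueError(f"series {self.label!r}: timepoints must be strictly increasing")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class WarpPath:
    """Ordered 1-based index pairs matched between series A and B."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        pairs = tuple((int(i), int(j)) for i, j in self.pairs)
        object.__setattr__(self, "pairs", pairs)
        if not pairs:
            raise ValueError("warp path must be non-empty")
        if pairs[0] != (1, 1):
            raise ValueError(f"warp path must start at (1, 1), got {pairs[0]}")
        for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
            if (i1 - i0, j1 - j0) not in {(1, 0), (0, 1), (1, 1)}:
                raise ValueError(
                    f"invalid warp step from ({i0}, {j0}) to ({i1}, {j1})"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    @property
    def end(self) -> tuple[int, int]:
        return self.pairs[-1]


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal DTW alignment: accumulated cost plus one optimal path."""

    distance: float
    path: WarpPath
    step_pattern: StepPattern = "fewer_delays"
    local_distance: LocalDistance = "absolute"


@dataclass(frozen=True)
class DtwConfig:
    """Alignment options shared by a whole screening run."""

    step_pattern: StepPattern = "fewer_delays"
    local_distance: LocalDistance = "absolute"

    def __post_init__(self):
        if self.step_pattern not in STEP_PATTERNS:
            raise ValueError(f"unknown step pattern {self.step_pattern!r}")
        if self.local_distance not in LOCAL_DISTANCES:
            raise ValueError(f"unknown local distance {self.local_distance!r}")


def scale_series(series: TimeSeries, mode: ScalingMode = "unit_variance") -> TimeSeries:
    """Rescale one series so entities and endpoints are comparable.

    ``unit_variance`` autoscales: subtract the mean and divide by the
    sample (t-1) standard deviation.  ``mean_center`` subtracts the mean
    only.  ``none`` returns the input unchanged.  Label and time points
    are preserved.

    Raises
    ------
    DegenerateSeriesError
        For ``unit_variance`` on a constant series (sd = 0); the caller
        may drop the entity with a warning.
    """
    if mode == "none":
        return series
    x = series.values
    if mode == "mean_center":
        return replace(series, values=x - x.mean())
    if mode == "unit_variance":
        sd = x.std(ddof=1)
        if sd == 0:
            raise DegenerateSeriesError(series.label)
        return replace(series, values=(x - x.mean()) / sd)
    raise ValueError(f"unknown scaling mode {mode!r}")


def _local_cost_matrix(a: np.ndarray, b: np.ndarray, local_distance: LocalDistance) -> np.ndarray:
    d = np.abs(a[:, None] - b[None, :])
    if local_distance == "squared":
        d = d * d
    elif local_distance != "absolute":
        raise ValueError(f"unknown local distance {local_distance!r}")
    return d


def _accumulate(d: np.ndarray, step_pattern: StepPattern) -> np.ndarray:
    """Fill the accumulated-cost matrix for one local-cost matrix."""
    ta, tb = d.shape
    D = np.empty_like(d)
    D[0, 0] = d[0, 0]
    D[1:, 0] = np.cumsum(d[1:, 0]) + d[0, 0]
    D[0, 1:] = np.cumsum(d[0, 1:]) + d[0, 0]
    if step_pattern == "fewer_delays":
        for i in range(1, ta):
            row, prev = D[i], D[i - 1]
            for j in range(1, tb):
                row[j] = d[i, j] + min(prev[j], row[j - 1], prev[j - 1])
    elif step_pattern == "symmetric_weighted":
        for i in range(1, ta):
            row, prev = D[i], D[i - 1]
            for j in range(1, tb):
                dij = d[i, j]
                row[j] = min(prev[j] + dij, row[j - 1] + dij, prev[j - 1] + 2 * dij)
    else:
        raise ValueError(f"unknown step pattern {step_pattern!r}")
    return D


def _traceback(d: np.ndarray, D: np.ndarray, step_pattern: StepPattern) -> WarpPath:
    """Recover one optimal path; ties prefer diagonal, then (i-1, j), then (i, j-1)."""
    i, j = d.shape[0] - 1, d.shape[1] - 1
    pairs = [(i + 1, j + 1)]
    diag_w = 2.0 if step_pattern == "symmetric_weighted" else 1.0
    while i > 0 or j > 0:
        if i == 0:
            j -= 1
        elif j == 0:
            i -= 1
        else:
            here = D[i, j]
            dij = d[i, j]
            if np.isclose(here, D[i - 1, j - 1] + diag_w * dij):
                i, j = i - 1, j - 1
            elif np.isclose(here, D[i - 1, j] + dij):
                i -= 1
            else:
                j -= 1
        pairs.append((i + 1, j + 1))
    pairs.reverse()
    return WarpPath(tuple(pairs))


def dtw_align(
    a: TimeSeries,
    b: TimeSeries,
    step_pattern: StepPattern = "fewer_delays",
    local_distance: LocalDistance = "absolute",
) -> AlignmentResult:
    """Optimal monotone boundary-complete alignment of two time courses.

    The caller is responsible for scaling the two series consistently.
    Lengths may differ (matched mode with unequal time grids).

    Returns
    -------
    AlignmentResult
        Minimum accumulated local cost over all warp paths under the
        chosen step pattern, plus one optimal path (deterministic
        tie-breaking: diagonal first, then vertical, then horizontal).
    """
    d = _local_cost_matrix(a.values, b.values, local_distance)
    D = _accumulate(d, step_pattern)
    path = _traceback(d, D, step_pattern)
    return AlignmentResult(
        distance=float(D[-1, -1]),
        path=path,
        step_pattern=step_pattern,
        local_distance=local_distance,
    )


def dtw_distance_batch(
    A: np.ndarray,
    B: np.ndarray,
    step_pattern: StepPattern = "fewer_delays",
    local_distance: LocalDistance = "absolute",
) -> np.ndarray:
    """DTW distances for a batch of series pairs, vectorised over the batch.

    ``A`` is ``(m, ta)`` and ``B`` is ``(m, tb)``; row k of A is aligned
    with row k of B.  Only distances are computed (no paths), which makes
    permutation nulls cheap: the dynamic program loops over the (ta, tb)
    grid once while the minimum is taken elementwise across the batch.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] != B.shape[0]:
        raise ValueError(f"batch shapes must be (m, ta) and (m, tb); got {A.shape} and {B.shape}")
    d = np.abs(A[:, :, None] - B[:, None, :])
    if local_distance == "squared":
        d = d * d
    elif local_distance != "absolute":
        raise ValueError(f"unknown local distance {local_distance!r}")
    m, ta, tb = d.shape
    D = np.empty_like(d)
    D[:, 0, 0] = d[:, 0, 0]
    D[:, 1:, 0] = np.cumsum(d[:, 1:, 0], axis=1) + d[:, 0, 0][:, None]
    D[:, 0, 1:] = np.cumsum(d[:, 0, 1:], axis=1) + d[:, 0, 0][:, None]
    if step_pattern == "fewer_delays":
        for i in range(1, ta):
            for j in range(1, tb):
                best = np.minimum(D[:, i - 1, j], D[:, i, j - 1])
                np.minimum(best, D[:, i - 1, j - 1], out=best)
                D[:, i, j] = d[:, i, j] + best
    elif step_pattern == "symmetric_weighted":
        for i in range(1, ta):
            for j in range(1, tb):
                dij = d[:, i, j]
                best = np.minimum(D[:, i - 1, j], D[:, i, j - 1]) + dij
                np.minimum(best, D[:, i - 1, j - 1] + 2 * dij, out=best)
                D[:, i, j] = best
    else:
        raise ValueError(f"unknown step pattern {step_pattern!r}")
    return D[:, -1, -1]
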