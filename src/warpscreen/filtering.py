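"""Pre-filter entities to complete rows with a significant time course.

Screening every measured entity is wasteful and statistically costly:
flat profiles cannot align meaningfully and constant rows break
unit-variance scaling.  The filter keeps a row only if

* it has no missing values, and
* at least one time point deviates from the row's own mean by at least
  ``z_threshold`` sample standard deviations (computed across that row's
  time points).

The 2-SD default means a row must contain at least one pronounced
excursion; linear ramps and constant rows fail it.  The criterion is a
z-score, so rescaling a row by a positive constant never changes its
retained/dropped status.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import EntityMatrix


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_dropped_missing: int
    n_dropped_flat: int
    n_retained: int

    def __post_init__(self):
        if self.n_input != self.n_dropped_missing + self.n_dropped_flat + self.n_retained:
            raise ValueError("filter counts do not add up")


def filter_time_courses(
    matrix: EntityMatrix, z_threshold: float = 2.0
) -> tuple[EntityMatrix, FilterReport]:
    """Drop incomplete rows, then rows without a z >= threshold excursion.

    Returns the retained submatrix (original row order) and the counts.
    An empty result is a warning condition for callers, not an error.
    """
    if matrix.t < 3:
        raise ValueError("need at least 3 time points to estimate a spread")
    values = matrix.values
    complete = np.all(np.isfinite(values), axis=1)
    spiky = np.zeros(matrix.n, dtype=bool)
    if complete.any():
        sub = values[complete]
        mean = sub.mean(axis=1)
        # sample sd across time points; constant rows (sd == 0) always drop
        sd = sub.std(axis=1, ddof=1)
        max_dev = np.abs(sub - mean[:, None]).max(axis=1)
        spiky[complete] = (sd > 0) & (max_dev >= z_threshold * sd)
    report = FilterReport(
        n_input=matrix.n,
        n_dropped_missing=int(np.sum(~complete)),
        n_dropped_flat=int(np.sum(complete & ~spiky)),
        n_retained=int(np.sum(spiky)),
    )
    return matrix.subset(spiky), report
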