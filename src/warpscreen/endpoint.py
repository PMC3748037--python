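"""Endpoint screen: every entity against every reference endpoint.

This is the tool's primary mode.  For each endpoint column the screen
scales the endpoint and every entity, computes the optimal DTW
alignment per entity, estimates a permutation p-value, applies
Benjamini-Hochberg correction across the family of n entities (one
family per endpoint), and flags entities with q at or below the run's
threshold.  A companion Pearson-correlation screen over the same
entities supports the comparison of the two approaches: DTW recovers
associations that correlation misses when responses are delayed or run
at different speeds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dtw import (
    DegenerateSeriesError,
    DtwConfig,
    TimeSeries,
    WarpPath,
    dtw_align,
    scale_series,
)
from .matrix import EndpointMatrix, EntityMatrix
from .significance import bh_adjust, permutation_pvalue


@dataclass(frozen=True)
class ScreenRecord:
    """One entity's result against one endpoint."""

    entity_label: str
    endpoint_label: str
    distance: float
    p_value: float
    q_value: float
    significant: bool
    path: WarpPath
    null_distances: np.ndarray = field(repr=False, default=None)


@dataclass
class ScreenResult:
    """All records for one endpoint, in input entity order."""

    endpoint_label: str
    records: list[ScreenRecord]
    q_threshold: float
    n_perm: int
    seed: int
    scaling: str
    dtw_config: DtwConfig
    dropped_labels: list[str] = field(default_factory=list)

    @property
    def significant_records(self) -> list[ScreenRecord]:
        return [r for r in self.records if r.significant]

    @property
    def best_record(self) -> ScreenRecord | None:
        """Most significant entity, reported whether or not it passed the threshold."""
        if not self.records:
            return None
        return min(self.records, key=lambda r: (r.q_value, r.p_value, r.distance))


@dataclass(frozen=True)
class CorrelationRecord:
    entity_label: str
    r: float
    p_value: float
    q_value: float
    significant_positive: bool


@dataclass(frozen=True)
class OverlapSummary:
    """DTW-vs-correlation agreement for one endpoint (comparison-table shape)."""

    endpoint_label: str
    n_corr: int
    n_dtw: int
    n_overlap: int
    pct_dtw_not_corr: int | None
    pct_corr_found_by_dtw: int | None

    def __post_init__(self):
        if self.n_overlap > min(self.n_corr, self.n_dtw):
            raise ValueError("overlap cannot exceed either margin count")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _entity_seed(run_seed: int, endpoint_index: int, entity_index: int) -> np.random.SeedSequence:
    # canonical per-entity stream: reproducible and independent of iteration order
    return np.random.SeedSequence([int(run_seed), int(endpoint_index), int(entity_index)])


def run_endpoint_screen(
    entities: EntityMatrix,
    endpoints: EndpointMatrix,
    out_dirs: list | None = None,
    scaling: str = "unit_variance",
    q_threshold: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    dtw_config: DtwConfig = DtwConfig(),
    image_format: str = "jpg",
) -> list[ScreenResult]:
    """Screen all entities against all endpoints; one result per endpoint.

    ``out_dirs`` (one directory per endpoint) enables the file outputs:
    significant-entity list, run summary, per-significant-entity warp
    plots and the two null-distance histograms.  With ``out_dirs=None``
    the screen runs purely in memory.

    Entities with zero variance under unit-variance scaling are dropped
    from the screen (and from the correlation arm) with a warning; they
    are listed in each result's ``dropped_labels``.
    """
    if entities.t != endpoints.t:
        raise ValueError(
            f"entity matrix is {entities.n}x{entities.t} but endpoint matrix is "
            f"{endpoints.t}x{endpoints.e}: time-point counts differ"
        )
    if out_dirs is not None and len(out_dirs) != endpoints.e:
        raise ValueError(f"{len(out_dirs)} output directories for {endpoints.e} endpoints")

    scaled_entities: list[TimeSeries] = []
    entity_indices: list[int] = []
    dropped: list[str] = []
    for i in range(entities.n):
        try:
            scaled_entities.append(scale_series(entities.row(i), scaling))
            entity_indices.append(i)
        except DegenerateSeriesError:
            warnings.warn(
                f"dropping zero-variance entity {entities.labels[i]!r} "
                f"(cannot be unit-variance scaled)"
            )
            dropped.append(entities.labels[i])

    results = []
    for j in range(endpoints.e):
        endpoint = scale_series(endpoints.column(j), scaling)
        records: list[ScreenRecord] = []
        raw = []
        for i, entity in zip(entity_indices, scaled_entities):
            alignment = dtw_align(
                entity, endpoint, dtw_config.step_pattern, dtw_config.local_distance
            )
            null = permutation_pvalue(
                entity,
                endpoint,
                n_perm=n_perm,
                seed=_entity_seed(seed, j, i),
                dtw_config=dtw_config,
            )
            raw.append((entity.label, alignment, null))
        qset = bh_adjust([null.p_value for _, _, null in raw], threshold=q_threshold)
        for (label, alignment, null), q in zip(raw, qset.q_values):
            records.append(
                ScreenRecord(
                    entity_label=label,
                    endpoint_label=endpoint.label,
                    distance=alignment.distance,
                    p_value=null.p_value,
                    q_value=float(q),
                    significant=bool(q <= q_threshold),
                    path=alignment.path,
                    null_distances=null.null_distances,
                )
            )
        result = ScreenResult(
            endpoint_label=endpoint.label,
            records=records,
            q_threshold=q_threshold,
            n_perm=n_perm,
            seed=seed,
            scaling=scaling,
            dtw_config=dtw_config,
            dropped_labels=list(dropped),
        )
        results.append(result)
        if out_dirs is not None:
            from .reports import write_screen_outputs

            write_screen_outputs(
                result,
                out_dirs[j],
                entities=entities,
                endpoints=endpoints,
                image_format=image_format,
            )
    return results


def correlate_entities(
    entities: EntityMatrix, endpoint: TimeSeries, q_threshold: float = 0.05
) -> list[CorrelationRecord]:
    """Pearson-correlation screen of every entity against one endpoint.

    Two-sided p-values come from the t-distribution test of r; BH is
    applied across the n entities and ``significant_positive`` requires
    both q <= threshold and r > 0 (anticorrelated profiles never count).
    Constant entities have undefined r and are excluded with a warning.
    """
    if entities.t != len(endpoint):
        raise ValueError(
            f"entity matrix has t={entities.t} but endpoint {endpoint.label!r} "
            f"has {len(endpoint)} time points"
        )
    if np.std(endpoint.values) == 0:
        raise ValueError(f"endpoint {endpoint.label!r} is constant; correlation undefined")
    kept, rs, ps = [], [], []
    for i in range(entities.n):
        row = entities.values[i]
        if not np.all(np.isfinite(row)) or np.std(row) == 0:
            warnings.warn(
                f"excluding entity {entities.labels[i]!r} from correlation "
                f"(constant or incomplete)"
            )
            continue
        r, p = stats.pearsonr(row, endpoint.values)
        kept.append(entities.labels[i])
        rs.append(float(r))
        # a numerically perfect correlation gives p == 0; clamp into (0, 1]
        ps.append(max(float(p), np.finfo(float).tiny))
    if not kept:
        return []
    qset = bh_adjust(ps, threshold=q_threshold)
    return [
        CorrelationRecord(
            entity_label=label,
            r=r,
            p_value=p,
            q_value=float(q),
            significant_positive=bool(q <= q_threshold and r > 0),
        )
        for label, r, p, q in zip(kept, rs, ps, qset.q_values)
    ]


def overlap_stats(
    dtw_significant: set[str],
    corr_significant_positive: set[str],
    endpoint_label: str = "",
) -> OverlapSummary:
    """Agreement between the DTW and positive-correlation hit lists.

    Percentages are rounded half away from zero to integers; a zero
    denominator leaves the percentage undefined (``None``, rendered as
    a dash in reports).
    """
    n_dtw = len(dtw_significant)
    n_corr = len(corr_significant_positive)
    n_overlap = len(dtw_significant & corr_significant_positive)
    pct_dtw_not_corr = (
        _round_half_away(100 * (n_dtw - n_overlap) / n_dtw) if n_dtw else None
    )
    pct_corr_found_by_dtw = (
        _round_half_away(100 * n_overlap / n_corr) if n_corr else None
    )
    return OverlapSummary(
        endpoint_label=endpoint_label,
        n_corr=n_corr,
        n_dtw=n_dtw,
        n_overlap=n_overlap,
        pct_dtw_not_corr=pct_dtw_not_corr,
        pct_corr_found_by_dtw=pct_corr_found_by_dtw,
    )
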