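"""Matched screen: the same entity compared across two experiments.

Rows are paired by label intersection — gene A under condition 1 against
gene A under condition 2 — and the two experiments may use different
time grids (t1 != t2 is fine; the warp path then spans (1,1)..(t1,t2)).
Labels present in only one matrix are skipped and counted.

Results are invariant to swapping the two matrices: DTW distances are
symmetric under both step patterns, and the permutation streams are
seeded canonically per label (with the stream-to-series assignment
resolved by the series' own values, not by which matrix happened to be
passed first), so the null distribution is identical either way.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .dtw import (
    DegenerateSeriesError,
    DtwConfig,
    TimeSeries,
    WarpPath,
    dtw_align,
    dtw_distance_batch,
    scale_series,
)
from .matrix import EntityMatrix
from .significance import PermutationNull, _random_permutations, bh_adjust


@dataclass(frozen=True)
class MatchedRecord:
    entity_label: str
    distance: float
    p_value: float
    q_value: float
    significant: bool
    path: WarpPath
    null_distances: np.ndarray = field(repr=False, default=None)


@dataclass
class MatchedResult:
    records: list[MatchedRecord]
    q_threshold: float
    n_perm: int
    seed: int
    scaling: str
    dtw_config: DtwConfig
    unpaired_a: list[str] = field(default_factory=list)
    unpaired_b: list[str] = field(default_factory=list)
    dropped_labels: list[str] = field(default_factory=list)

    @property
    def significant_records(self) -> list[MatchedRecord]:
        return [r for r in self.records if r.significant]

    @property
    def best_record(self) -> MatchedRecord | None:
        if not self.records:
            return None
        return min(self.records, key=lambda r: (r.q_value, r.p_value, r.distance))


def _label_seed(run_seed: int, label: str) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(run_seed), zlib.crc32(label.encode("utf-8"))])


def _matched_null(
    a: TimeSeries,
    b: TimeSeries,
    n_perm: int,
    seed_sequence: np.random.SeedSequence,
    dtw_config: DtwConfig,
) -> PermutationNull:
    """Permutation null with swap-invariant stream assignment.

    Two child streams are spawned from the label's seed; which stream
    permutes which series is decided by comparing the scaled values, so
    exchanging the input matrices reproduces the identical null set.
    """
    child_a, child_b = seed_sequence.spawn(2)
    if tuple(a.values) > tuple(b.values):
        child_a, child_b = child_b, child_a
    perm_a = a.values[_random_permutations(np.random.default_rng(child_a), n_perm, len(a))]
    perm_b = b.values[_random_permutations(np.random.default_rng(child_b), n_perm, len(b))]
    null = dtw_distance_batch(perm_a, perm_b, dtw_config.step_pattern, dtw_config.local_distance)
    observed = dtw_align(a, b, dtw_config.step_pattern, dtw_config.local_distance).distance
    p = (1 + int(np.sum(null <= observed))) / (n_perm + 1)
    return PermutationNull(observed_distance=observed, null_distances=null, p_value=p)


def run_matched_screen(
    matrix_a: EntityMatrix,
    matrix_b: EntityMatrix,
    out_dir=None,
    scaling: str = "unit_variance",
    q_threshold: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    dtw_config: DtwConfig = DtwConfig(),
    image_format: str = "jpg",
) -> MatchedResult:
    """Compare each shared row label across the two matrices.

    The analysis runs on the label intersection only, in ``matrix_a``'s
    row order; BH correction is applied across that intersection.  An
    empty intersection is an error ("no comparable entities").
    """
    labels_b = set(matrix_b.labels)
    shared = [lab for lab in matrix_a.labels if lab in labels_b]
    if not shared:
        raise ValueError("no comparable entities: the row-label intersection is empty")
    unpaired_a = [lab for lab in matrix_a.labels if lab not in labels_b]
    labels_a = set(matrix_a.labels)
    unpaired_b = [lab for lab in matrix_b.labels if lab not in labels_a]

    index_a = {lab: i for i, lab in enumerate(matrix_a.labels)}
    index_b = {lab: i for i, lab in enumerate(matrix_b.labels)}

    raw, dropped = [], []
    for label in shared:
        try:
            a = scale_series(matrix_a.row(index_a[label]), scaling)
            b = scale_series(matrix_b.row(index_b[label]), scaling)
        except DegenerateSeriesError:
            warnings.warn(f"dropping zero-variance entity {label!r}")
            dropped.append(label)
            continue
        alignment = dtw_align(a, b, dtw_config.step_pattern, dtw_config.local_distance)
        null = _matched_null(a, b, n_perm, _label_seed(seed, label), dtw_config)
        raw.append((label, alignment, null))

    records: list[MatchedRecord] = []
    if raw:
        qset = bh_adjust([null.p_value for _, _, null in raw], threshold=q_threshold)
        for (label, alignment, null), q in zip(raw, qset.q_values):
            records.append(
                MatchedRecord(
                    entity_label=label,
                    distance=alignment.distance,
                    p_value=null.p_value,
                    q_value=float(q),
                    significant=bool(q <= q_threshold),
                    path=alignment.path,
                    null_distances=null.null_distances,
                )
            )
    result = MatchedResult(
        records=records,
        q_threshold=q_threshold,
        n_perm=n_perm,
        seed=seed,
        scaling=scaling,
        dtw_config=dtw_config,
        unpaired_a=unpaired_a,
        unpaired_b=unpaired_b,
        dropped_labels=dropped,
    )
    if out_dir is not None:
        from .reports import write_matched_outputs

        write_matched_outputs(
            result, out_dir, matrix_a=matrix_a, matrix_b=matrix_b, image_format=image_format
        )
    return result
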