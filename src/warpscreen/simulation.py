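"""Synthetic benchmark for the matched screen: smooth series, shifts, noise.

The benchmark emulates paired experiments in which the same entity
responds with the same underlying pattern but delayed and noisier in the
second experiment.  Construction:

* every *mother* series is a smooth random curve of length
  ``length + max_shift`` (a cubic spline through iid standard-normal
  knots), smooth because biological time courses are — and because
  smoothness is exactly what makes permutation p-values anti-
  conservative, a behaviour the benchmark is designed to expose;
* the first-experiment row is the mother's first ``length`` points; the
  second-experiment row is a window starting ``shift`` points later
  (so shifted copies share no wrap-around artefacts), plus iid Gaussian
  noise with sd equal to ``noise_level * noise_step`` times the mother's
  own sd (defaults: 10%..100% of signal sd over 10 levels);
* (shift, noise) cells are assigned round-robin so every cell holds the
  same number of matched rows;
* decoy rows are independent smooth series sharing labels across the two
  sets, so the screen compares two unrelated smooth curves.

Scoring mirrors the two questions one asks of such a screen: how often
is a truly matched pair flagged significant at the stated FDR, and how
often does the optimal warp path recover the intended shift exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .dtw import TimeSeries, WarpPath
from .matched import MatchedRecord, MatchedResult
from .matrix import EntityMatrix, write_entity_matrix


@dataclass
class BenchmarkSet:
    """Paired synthetic matrices plus the ground-truth corruption table.

    ``truth`` is indexed by the second-set row label with columns
    ``matched_index`` (row index into ``set_a``, -1 for decoys),
    ``shift`` and ``noise_level`` (pandas NA for decoys).
    """

    set_a: EntityMatrix
    set_b: EntityMatrix
    truth: pd.DataFrame
    mother_length: int
    max_shift: int
    n_noise_levels: int
    noise_step: float

    @property
    def length(self) -> int:
        return self.set_a.t

    def matched_labels(self) -> list[str]:
        return self.truth.index[self.truth["matched_index"] >= 0].tolist()

    def decoy_labels(self) -> list[str]:
        return self.truth.index[self.truth["matched_index"] < 0].tolist()


@dataclass
class EvaluationGrid:
    """Percent detected and percent exact-path recovery per (noise, shift) cell.

    Rows are noise levels (lowest first), columns are shifts (0 first).
    """

    detection_pct: np.ndarray
    exact_path_pct: np.ndarray
    decoy_detection_pct: float
    fdr: float
    shifts: np.ndarray
    noise_levels: np.ndarray

    def __post_init__(self):
        for grid in (self.detection_pct, self.exact_path_pct):
            if np.any((grid < 0) | (grid > 100)):
                raise ValueError("percentages must lie in [0, 100]")

    def detection_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.detection_pct,
            index=pd.Index(self.noise_levels, name="noise_level"),
            columns=pd.Index(self.shifts, name="shift"),
        )

    def exact_path_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.exact_path_pct,
            index=pd.Index(self.noise_levels, name="noise_level"),
            columns=pd.Index(self.shifts, name="shift"),
        )


def _smooth_values(length: int, rng: np.random.Generator) -> np.ndarray:
    n_knots = max(4, math.ceil(length / 5))
    positions = np.linspace(1, length, n_knots)
    knots = rng.standard_normal(n_knots)
    return CubicSpline(positions, knots)(np.arange(1, length + 1))


def generate_smooth_series(
    length: int, seed: int | np.random.Generator | None = 0, label: str = "smooth"
) -> TimeSeries:
    """A smooth random time course: cubic spline through normal knots.

    ``max(4, ceil(length/5))`` knot values are drawn iid standard normal
    at evenly spaced positions spanning [1, length] and interpolated with
    a cubic spline evaluated at the integer positions.  Deterministic for
    a given seed.
    """
    if length < 4:
        raise ValueError("smooth series need length >= 4")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return TimeSeries(label, _smooth_values(length, rng), np.arange(1, length + 1))


def make_benchmark(
    n_matched: int = 10000,
    n_decoys: int = 1000,
    length: int = 20,
    max_shift: int = 9,
    n_noise_levels: int = 10,
    noise_step: float = 0.1,
    seed: int = 0,
) -> BenchmarkSet:
    """Generate the paired benchmark matrices and their truth table.

    The default configuration is the full-scale study design: 10,000
    matched rows balanced over 10 shifts (0-9) x 10 noise levels plus
    1,000 decoy rows, all of length 20.  ``n_matched`` not divisible by
    the number of cells is truncated to the largest balanced count, with
    a warning.
    """
    if length < 4:
        raise ValueError("series length must be >= 4")
    if max_shift >= length:
        raise ValueError("max_shift must be smaller than the series length")
    n_cells = (max_shift + 1) * n_noise_levels
    if n_matched % n_cells:
        balanced = (n_matched // n_cells) * n_cells
        warnings.warn(
            f"n_matched={n_matched} is not divisible by {n_cells} (shift x noise "
            f"cells); truncating to {balanced} for balanced cells"
        )
        n_matched = balanced
    rng = np.random.default_rng(seed)
    mother_length = length + max_shift
    timepoints = np.arange(1, length + 1, dtype=float)
    width = len(str(n_matched + n_decoys))

    labels, rows_a, rows_b = [], [], []
    matched_index, shifts, noise_levels = [], [], []
    for m in range(n_matched):
        cell = m % n_cells
        shift = cell // n_noise_levels
        noise_level = cell % n_noise_levels + 1
        mother = _smooth_values(mother_length, rng)
        noise_sd = noise_level * noise_step * np.std(mother, ddof=1)
        labels.append(f"e{m + 1:0{width}d}")
        rows_a.append(mother[:length])
        rows_b.append(mother[shift : shift + length] + rng.normal(0.0, noise_sd, length))
        matched_index.append(m)
        shifts.append(shift)
        noise_levels.append(noise_level)
    for k in range(n_decoys):
        labels.append(f"e{n_matched + k + 1:0{width}d}")
        rows_a.append(_smooth_values(length, rng))
        rows_b.append(_smooth_values(length, rng))
        matched_index.append(-1)
        shifts.append(pd.NA)
        noise_levels.append(pd.NA)

    truth = pd.DataFrame(
        {
            "matched_index": pd.array(matched_index, dtype="Int64"),
            "shift": pd.array(shifts, dtype="Int64"),
            "noise_level": pd.array(noise_levels, dtype="Int64"),
        },
        index=pd.Index(labels, name="label"),
    )
    set_a = EntityMatrix(labels=list(labels), values=np.array(rows_a), timepoints=timepoints)
    set_b = EntityMatrix(labels=list(labels), values=np.array(rows_b), timepoints=timepoints)
    return BenchmarkSet(
        set_a=set_a,
        set_b=set_b,
        truth=truth,
        mother_length=mother_length,
        max_shift=max_shift,
        n_noise_levels=n_noise_levels,
        noise_step=noise_step,
    )


def intended_path(length: int, shift: int) -> WarpPath:
    """The ground-truth warp for a pair where B's window lags A's by ``shift``.

    B[j] equals A[j + shift] on the overlap, so the minimal-step
    boundary-complete path holds B at its first point while A advances
    through the un-shared prefix, runs diagonally across the overlap, and
    holds A at its last point through B's un-shared suffix:
    (1,1)..(shift+1,1), diagonal to (length, length-shift), then
    (length, length-shift+1)..(length, length).
    """
    if not 0 <= shift < length:
        raise ValueError(f"shift must satisfy 0 <= shift < length, got {shift}")
    pairs = [(i, 1) for i in range(1, shift + 2)]
    pairs += [(shift + 1 + k, 1 + k) for k in range(1, length - shift)]
    pairs += [(length, j) for j in range(length - shift + 1, length + 1)]
    return WarpPath(tuple(pairs))


def evaluate_benchmark(
    benchmark: BenchmarkSet,
    records: list[MatchedRecord] | MatchedResult,
    fdr: float = 0.05,
) -> EvaluationGrid:
    """Score a matched screen against the benchmark's ground truth.

    Detection means q <= ``fdr``; exact-path recovery means the returned
    warp path equals, pair for pair, the intended path for the row's true
    shift (co-optimal alternatives count as failures).  Decoy detection
    is the percentage of unmatched rows flagged significant.
    """
    if isinstance(records, MatchedResult):
        records = records.records
    by_label = {r.entity_label: r for r in records}
    missing = [lab for lab in benchmark.truth.index if lab not in by_label]
    if missing:
        raise ValueError(
            f"records do not cover the benchmark: {len(missing)} labels missing "
            f"(first: {missing[:3]})"
        )
    length = benchmark.length
    shifts = np.arange(benchmark.max_shift + 1)
    noise_levels = np.arange(1, benchmark.n_noise_levels + 1)
    detected = np.zeros((len(noise_levels), len(shifts)))
    exact = np.zeros_like(detected)
    totals = np.zeros_like(detected)
    n_decoys = n_decoys_hit = 0
    for label, row in benchmark.truth.iterrows():
        record = by_label[label]
        hit = record.q_value <= fdr
        if row["matched_index"] < 0:
            n_decoys += 1
            n_decoys_hit += hit
            continue
        i = int(row["noise_level"]) - 1
        j = int(row["shift"])
        totals[i, j] += 1
        detected[i, j] += hit
        exact[i, j] += record.path.pairs == intended_path(length, j).pairs
    if np.any(totals == 0):
        raise ValueError("benchmark has empty (noise, shift) cells; cannot form percentages")
    return EvaluationGrid(
        detection_pct=100 * detected / totals,
        exact_path_pct=100 * exact / totals,
        decoy_detection_pct=100 * n_decoys_hit / n_decoys if n_decoys else float("nan"),
        fdr=fdr,
        shifts=shifts,
        noise_levels=noise_levels,
    )


def write_benchmark(benchmark: BenchmarkSet, out_dir) -> None:
    """Write the two matrices and the truth table as TSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_entity_matrix(benchmark.set_a, out / "set_a.tsv")
    write_entity_matrix(benchmark.set_b, out / "set_b.tsv")
    benchmark.truth.to_csv(out / "truth.tsv", sep="\t")


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", index_col="label")
    return truth.astype({c: "Int64" for c in ("matched_index", "shift", "noise_level")})


def load_benchmark(out_dir) -> BenchmarkSet:
    """Reload a benchmark written by :func:`write_benchmark`.

    ``max_shift`` and ``n_noise_levels`` are recovered from the truth
    table; ``noise_step`` is not stored (it is not needed for scoring)
    and is reloaded as NaN.
    """
    from .matrix import read_entity_matrix

    out = Path(out_dir)
    set_a = read_entity_matrix(out / "set_a.tsv")
    set_b = read_entity_matrix(out / "set_b.tsv")
    truth = read_truth(out / "truth.tsv")
    max_shift = int(truth["shift"].max())
    return BenchmarkSet(
        set_a=set_a,
        set_b=set_b,
        truth=truth,
        mother_length=set_a.t + max_shift,
        max_shift=max_shift,
        n_noise_levels=int(truth["noise_level"].max()),
        noise_step=float("nan"),
    )


def write_evaluation(grid: EvaluationGrid, out_dir, image_format: str = "jpg") -> None:
    """Write the evaluation grids as TSV plus two heat-map panels."""
    from .reports import plot_evaluation_heatmaps

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid.detection_frame().to_csv(out / "detection_pct.tsv", sep="\t")
    grid.exact_path_frame().to_csv(out / "exact_path_pct.tsv", sep="\t")
    with open(out / "decoy_detection.txt", "w") as fh:
        fh.write(
            f"decoy_detection_pct\t{grid.decoy_detection_pct:.2f}\nfdr\t{grid.fdr}\n"
        )
    plot_evaluation_heatmaps(grid, out, image_format=image_format)
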