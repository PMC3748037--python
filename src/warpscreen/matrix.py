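"""Labelled expression-matrix containers and their TSV dialect.

Two orientations are used throughout:

* an *entity matrix* is ``n x t`` — one row per measured entity (gene,
  metabolite, ...), one column per time point;
* an *endpoint matrix* is ``t x e`` — one row per time point, one column
  per reference endpoint (phenotypic marker, cell-cycle fraction, or
  time itself).

On disk both are tab-separated with a header row and a leading label
column.  Empty cells and the tokens ``NA``/``NaN``/``nan`` are read as
missing; missing values are allowed on input only and are removed by the
pre-filter before any screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

_NA_TOKENS = ["", "NA", "NaN", "nan"]


class MatrixParseError(ValueError):
    pass


def _check_unique(labels, what: str):
    seen = pd.Index(labels)
    if seen.has_duplicates:
        dup = seen[seen.duplicated()].unique().tolist()
        raise MatrixParseError(f"duplicate {what} label(s): {dup}")


@dataclass
class EntityMatrix:
    """n entities x t time points, with unique row labels."""

    labels: list[str]
    values: np.ndarray
    timepoints: np.ndarray

    def __post_init__(self):
        self.labels = [str(lab) for lab in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("entity matrix must be 2-D")
        n, t = self.values.shape
        if len(self.labels) != n:
            raise ValueError(f"{len(self.labels)} labels for {n} rows")
        if len(self.timepoints) != t:
            raise ValueError(f"{len(self.timepoints)} time points for {t} columns")
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        _check_unique(self.labels, "entity")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def t(self) -> int:
        return self.values.shape[1]

    def row(self, i: int):
        from .dtw import TimeSeries

        return TimeSeries(self.labels[i], self.values[i], self.timepoints)

    def subset(self, keep: np.ndarray) -> "EntityMatrix":
        keep = np.asarray(keep)
        return EntityMatrix(
            labels=[lab for lab, k in zip(self.labels, keep) if k],
            values=self.values[keep.astype(bool)],
            timepoints=self.timepoints,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.timepoints)


@dataclass
class EndpointMatrix:
    """t time points x e endpoints; no missing values allowed."""

    labels: list[str]
    values: np.ndarray
    timepoints: np.ndarray

    def __post_init__(self):
        self.labels = [str(lab) for lab in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("endpoint matrix must be 2-D")
        t, e = self.values.shape
        if len(self.labels) != e:
            raise ValueError(f"{len(self.labels)} labels for {e} endpoint columns")
        if len(self.timepoints) != t:
            raise ValueError(f"{len(self.timepoints)} time points for {t} rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("endpoint matrix must not contain missing values")
        _check_unique(self.labels, "endpoint")

    @property
    def t(self) -> int:
        return self.values.shape[0]

    @property
    def e(self) -> int:
        return self.values.shape[1]

    def column(self, j: int):
        from .dtw import TimeSeries

        return TimeSeries(self.labels[j], self.values[:, j], self.timepoints)


def _read_frame(path) -> pd.DataFrame:
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=_NA_TOKENS,
            keep_default_na=False,
            float_precision="round_trip",
        )
    except (pd.errors.ParserError, ValueError) as exc:
        raise MatrixParseError(f"{path}: {exc}") from exc
    for col in frame.columns:
        if not np.issubdtype(frame[col].dtype, np.number):
            bad = frame[col][pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()]
            line = int(frame.index.get_loc(bad.index[0])) + 2 if len(bad) else "?"
            raise MatrixParseError(
                f"{path}: non-numeric cell in column {col!r} (line {line})"
            )
    return frame


def read_entity_matrix(path, timepoints=None) -> EntityMatrix:
    """Read an n x t TSV (rows entities, columns time points).

    Column headers are used as the numeric time points unless an explicit
    ``timepoints`` vector is supplied.
    """
    frame = _read_frame(path)
    _check_unique(frame.index, "entity")
    if timepoints is None:
        try:
            timepoints = frame.columns.astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise MatrixParseError(
                f"{path}: column headers are not numeric time points; "
                f"pass timepoints explicitly"
            ) from exc
    return EntityMatrix(
        labels=frame.index.tolist(), values=frame.to_numpy(float), timepoints=np.asarray(timepoints, float)
    )


def read_endpoint_matrix(path, timepoints=None) -> EndpointMatrix:
    """Read a t x e TSV (rows time points, columns endpoints)."""
    frame = _read_frame(path)
    if frame.isna().any().any():
        raise MatrixParseError(f"{path}: endpoint matrix contains missing values")
    if timepoints is None:
        try:
            timepoints = frame.index.astype(float).to_numpy()
        except (TypeError, ValueError) as exc:
            raise MatrixParseError(
                f"{path}: row labels are not numeric time points; "
                f"pass timepoints explicitly"
            ) from exc
    return EndpointMatrix(
        labels=[str(c) for c in frame.columns],
        values=frame.to_numpy(float),
        timepoints=np.asarray(timepoints, float),
    )


def write_entity_matrix(matrix: EntityMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # %.17g keeps write -> read round trips bit-identical
    matrix.to_frame().to_csv(path, sep="\t", index_label="label", float_format="%.17g")


def write_endpoint_matrix(matrix: EndpointMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(matrix.values, index=matrix.timepoints, columns=matrix.labels)
    frame.to_csv(path, sep="\t", index_label="time", float_format="%.17g")


def read_timepoints(path) -> np.ndarray:
    """Read a one-column (or whitespace separated) numeric time-point vector."""
    values = np.loadtxt(path, dtype=float).ravel()
    if np.any(np.diff(values) <= 0):
        raise MatrixParseError(f"{path}: timepoints must be strictly increasing")
    return values
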