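"""Text reports and diagnostic plots for screening runs.

Each screen writes, per output directory:

* ``significant_entities.txt`` — label, distance, p and q per line,
  sorted by q then p then label;
* ``run_summary.txt`` — every parameter needed to replay the run, the
  counts, and the most significant entity found regardless of whether it
  reached the q-value threshold;
* ``<entity>_warp.<fmt>`` — a before/after panel per significant entity:
  the two scaled series overlaid on the supplied time axis, and the
  warped alignment with matched points connected;
* ``null_histogram.<fmt>`` — overlaid histograms of the real distances
  and the pooled permuted distances;
* ``best_entity_null.<fmt>`` — the most significant entity's permuted
  distances with its observed distance marked by an "X".

Images default to jpeg (png optional); image bytes are for inspection
only and carry no analytical contract.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .dtw import TimeSeries, WarpPath, scale_series
from .endpoint import ScreenRecord, ScreenResult
from .matched import MatchedResult
from .matrix import EndpointMatrix, EntityMatrix


@dataclass(frozen=True)
class RunSummary:
    function_name: str
    parameters: dict
    counts: dict
    best_entity: dict | None

    def render(self) -> str:
        lines = [f"function\t{self.function_name}"]
        for key, value in self.parameters.items():
            lines.append(f"param:{key}\t{value}")
        for key, value in self.counts.items():
            lines.append(f"count:{key}\t{value}")
        if self.best_entity is None:
            lines.append("best_entity\tnone")
        else:
            for key, value in self.best_entity.items():
                lines.append(f"best_entity:{key}\t{value}")
        return "\n".join(lines) + "\n"


def _safe_name(label: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]", "_", label)


def _sorted_records(records):
    return sorted(records, key=lambda r: (r.q_value, r.p_value, r.entity_label))


def _write_significant_list(records, path) -> None:
    with open(path, "w") as fh:
        fh.write("entity\tdistance\tp_value\tq_value\n")
        for r in _sorted_records(records):
            fh.write(f"{r.entity_label}\t{r.distance:.6g}\t{r.p_value:.6g}\t{r.q_value:.6g}\n")


def _serialize_path(path: WarpPath) -> str:
    return ";".join(f"{i}-{j}" for i, j in path)


def _parse_path(text: str) -> WarpPath:
    return WarpPath(tuple(tuple(int(x) for x in pair.split("-")) for pair in text.split(";")))


def write_matched_records(records, path) -> None:
    """Full per-entity record table (all entities, not only significant)."""
    with open(path, "w") as fh:
        fh.write("entity\tdistance\tp_value\tq_value\tsignificant\tpath\n")
        for r in records:
            fh.write(
                f"{r.entity_label}\t{r.distance:.10g}\t{r.p_value:.10g}\t"
                f"{r.q_value:.10g}\t{int(r.significant)}\t{_serialize_path(r.path)}\n"
            )


def read_matched_records(path):
    """Reload a record table written by :func:`write_matched_records`."""
    from .matched import MatchedRecord

    records = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            label, dist, p, q, sig, path_text = line.rstrip("\n").split("\t")
            records.append(
                MatchedRecord(
                    entity_label=label,
                    distance=float(dist),
                    p_value=float(p),
                    q_value=float(q),
                    significant=bool(int(sig)),
                    path=_parse_path(path_text),
                )
            )
    return records


def plot_warp(a: TimeSeries, b: TimeSeries, path: WarpPath, out_file) -> None:
    """Two panels: original overlay, then the warped alignment."""
    fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax0.plot(a.timepoints, a.values, "o-", label=a.label)
    ax0.plot(b.timepoints, b.values, "s--", label=b.label)
    ax0.set_xlabel("time")
    ax0.set_ylabel("scaled value")
    ax0.set_title("original")
    ax0.legend(fontsize=8)
    steps = np.arange(1, len(path) + 1)
    ai = np.array([i - 1 for i, _ in path])
    bj = np.array([j - 1 for _, j in path])
    ax1.plot(steps, a.values[ai], "o-", label=a.label)
    ax1.plot(steps, b.values[bj], "s--", label=b.label)
    for s, i, j in zip(steps, ai, bj):
        ax1.plot([s, s], [a.values[i], b.values[j]], color="grey", lw=0.5)
    ax1.set_xlabel("warp step")
    ax1.set_title("warped")
    ax1.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_file)
    plt.close(fig)


def plot_null_overlay(real_distances, null_distances, out_file) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(np.asarray(null_distances).ravel(), bins=30, density=True, alpha=0.5, label="permuted")
    ax.hist(np.asarray(real_distances).ravel(), bins=30, density=True, alpha=0.5, label="real")
    ax.set_xlabel("DTW distance")
    ax.set_ylabel("density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_file)
    plt.close(fig)


def plot_best_entity_null(record, out_file) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(np.asarray(record.null_distances), bins=30, alpha=0.7, label="permuted")
    ax.plot([record.distance], [0], "kx", markersize=14, markeredgewidth=3, label="observed")
    ax.set_xlabel("DTW distance")
    ax.set_ylabel("count")
    ax.set_title(record.entity_label)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_file)
    plt.close(fig)


def plot_evaluation_heatmaps(grid, out_dir, image_format: str = "jpg") -> None:
    """Two panels: detection and exact-path recovery over noise x shift."""
    out = Path(out_dir)
    for name, values in (
        ("detection_pct", grid.detection_pct),
        ("exact_path_pct", grid.exact_path_pct),
    ):
        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.imshow(values, vmin=0, vmax=100, aspect="auto", cmap="viridis")
        ax.set_xlabel("time shift (points)")
        ax.set_ylabel("noise level (low at top)")
        ax.set_xticks(range(len(grid.shifts)), grid.shifts)
        ax.set_yticks(range(len(grid.noise_levels)), grid.noise_levels)
        fig.colorbar(im, ax=ax, label="%")
        ax.set_title(name.replace("_", " "))
        fig.tight_layout()
        fig.savefig(out / f"{name}.{image_format}")
        plt.close(fig)


def write_screen_outputs(
    result: ScreenResult,
    out_dir,
    entities: EntityMatrix,
    endpoints: EndpointMatrix,
    image_format: str = "jpg",
) -> list[Path]:
    """Write the full per-endpoint file set; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    list_path = out / "significant_entities.txt"
    _write_significant_list(result.significant_records, list_path)
    written.append(list_path)

    best = result.best_record
    summary = RunSummary(
        function_name="endpoint_screen",
        parameters={
            "endpoint": result.endpoint_label,
            "scaling": result.scaling,
            "q_threshold": result.q_threshold,
            "n_perm": result.n_perm,
            "seed": result.seed,
            "step_pattern": result.dtw_config.step_pattern,
            "local_distance": result.dtw_config.local_distance,
        },
        counts={
            "entities_screened": len(result.records),
            "entities_dropped_zero_variance": len(result.dropped_labels),
            "significant": len(result.significant_records),
        },
        best_entity=None
        if best is None
        else {
            "label": best.entity_label,
            "distance": f"{best.distance:.6g}",
            "p_value": f"{best.p_value:.6g}",
            "q_value": f"{best.q_value:.6g}",
        },
    )
    summary_path = out / "run_summary.txt"
    summary_path.write_text(summary.render())
    written.append(summary_path)

    endpoint_idx = endpoints.labels.index(result.endpoint_label)
    endpoint_series = scale_series(endpoints.column(endpoint_idx), result.scaling)
    entity_index = {lab: i for i, lab in enumerate(entities.labels)}
    for record in result.significant_records:
        series = scale_series(entities.row(entity_index[record.entity_label]), result.scaling)
        img = out / f"{_safe_name(record.entity_label)}_warp.{image_format}"
        plot_warp(series, endpoint_series, record.path, img)
        written.append(img)

    real = [r.distance for r in result.records]
    pooled_null = (
        np.concatenate([r.null_distances for r in result.records])
        if result.records
        else np.array([])
    )
    hist_path = out / f"null_histogram.{image_format}"
    plot_null_overlay(real, pooled_null, hist_path)
    written.append(hist_path)
    if best is not None:
        best_path = out / f"best_entity_null.{image_format}"
        plot_best_entity_null(best, best_path)
        written.append(best_path)
    return written


def write_matched_outputs(
    result: MatchedResult,
    out_dir,
    matrix_a: EntityMatrix,
    matrix_b: EntityMatrix,
    image_format: str = "jpg",
) -> list[Path]:
    """Same file conventions as the endpoint screen, one directory total."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    list_path = out / "significant_entities.txt"
    _write_significant_list(result.significant_records, list_path)
    written.append(list_path)

    records_path = out / "records.tsv"
    write_matched_records(result.records, records_path)
    written.append(records_path)

    best = result.best_record
    summary = RunSummary(
        function_name="matched_screen",
        parameters={
            "scaling": result.scaling,
            "q_threshold": result.q_threshold,
            "n_perm": result.n_perm,
            "seed": result.seed,
            "step_pattern": result.dtw_config.step_pattern,
            "local_distance": result.dtw_config.local_distance,
        },
        counts={
            "entities_compared": len(result.records),
            "unpaired_first": len(result.unpaired_a),
            "unpaired_second": len(result.unpaired_b),
            "entities_dropped_zero_variance": len(result.dropped_labels),
            "significant": len(result.significant_records),
        },
        best_entity=None
        if best is None
        else {
            "label": best.entity_label,
            "distance": f"{best.distance:.6g}",
            "p_value": f"{best.p_value:.6g}",
            "q_value": f"{best.q_value:.6g}",
        },
    )
    summary_path = out / "run_summary.txt"
    summary_path.write_text(summary.render())
    written.append(summary_path)

    index_a = {lab: i for i, lab in enumerate(matrix_a.labels)}
    index_b = {lab: i for i, lab in enumerate(matrix_b.labels)}
    for record in result.significant_records:
        a = scale_series(matrix_a.row(index_a[record.entity_label]), result.scaling)
        b = scale_series(matrix_b.row(index_b[record.entity_label]), result.scaling)
        img = out / f"{_safe_name(record.entity_label)}_warp.{image_format}"
        plot_warp(a, b, record.path, img)
        written.append(img)

    real = [r.distance for r in result.records]
    pooled_null = (
        np.concatenate([r.null_distances for r in result.records])
        if result.records
        else np.array([])
    )
    hist_path = out / f"null_histogram.{image_format}"
    plot_null_overlay(real, pooled_null, hist_path)
    written.append(hist_path)
    if best is not None:
        best_path = out / f"best_entity_null.{image_format}"
        plot_best_entity_null(best, best_path)
        written.append(best_path)
    return written
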