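"""Endpoint screen, correlation arm, and the overlap summary."""

import numpy as np
import pytest

from warpscreen import (
    EndpointMatrix,
    EntityMatrix,
    TimeSeries,
    correlate_entities,
    overlap_stats,
    run_endpoint_screen,
)


def _entities(values, labels=None, timepoints=None):
    values = np.asarray(values, dtype=float)
    labels = labels or [f"g{i}" for i in range(values.shape[0])]
    tp = np.arange(values.shape[1], dtype=float) if timepoints is None else timepoints
    return EntityMatrix(labels=labels, values=values, timepoints=tp)


def _endpoints(columns, labels, timepoints=None):
    values = np.asarray(columns, dtype=float).T
    tp = np.arange(values.shape[0], dtype=float) if timepoints is None else timepoints
    return EndpointMatrix(labels=labels, values=values, timepoints=tp)


class TestRunEndpointScreen:
    def test_delayed_copy_of_endpoint_attains_smallest_distance(self, rng):
        t = 12
        endpoint = np.sin(np.linspace(0, 2 * np.pi, t))
        delayed = np.concatenate([[endpoint[0]] * 2, endpoint[:-2]])
        entities = _entities(
            [delayed, rng.standard_normal(t), rng.standard_normal(t)],
            labels=["delayed", "noise1", "noise2"],
        )
        endpoints = _endpoints([endpoint], ["marker"])
        (result,) = run_endpoint_screen(entities, endpoints, n_perm=99, seed=1)
        distances = {r.entity_label: r.distance for r in result.records}
        assert distances["delayed"] == min(distances.values())

    def test_time_point_count_mismatch_names_both_shapes(self, rng):
        entities = _entities(rng.standard_normal((3, 9)))
        endpoints = _endpoints([np.arange(8.0)], ["time"])
        with pytest.raises(ValueError, match="3x9.*8x1"):
            run_endpoint_screen(entities, endpoints, n_perm=9)

    def test_q_threshold_of_one_flags_everything(self, rng):
        entities = _entities(rng.standard_normal((5, 6)))
        endpoints = _endpoints([rng.standard_normal(6)], ["m"])
        (result,) = run_endpoint_screen(entities, endpoints, q_threshold=1.0, n_perm=19, seed=0)
        assert all(r.significant for r in result.records)

    def test_screening_endpoints_against_themselves_is_self_detecting(self, rng):
        t, e = 9, 3
        cols = rng.standard_normal((e, t))
        endpoints = _endpoints(list(cols), [f"m{j}" for j in range(e)])
        entities = _entities(cols, labels=[f"m{j}" for j in range(e)])
        results = run_endpoint_screen(entities, endpoints, n_perm=199, seed=2)
        for result in results:
            by_label = {r.entity_label: r for r in result.records}
            self_record = by_label[result.endpoint_label]
            assert self_record.distance == pytest.approx(0.0)
            assert self_record.p_value == min(r.p_value for r in result.records)

    def test_deterministic_and_order_independent_seeding(self, rng):
        values = rng.standard_normal((6, 7))
        entities = _entities(values)
        endpoints = _endpoints([rng.standard_normal(7)], ["m"])
        (first,) = run_endpoint_screen(entities, endpoints, n_perm=49, seed=7)
        (second,) = run_endpoint_screen(entities, endpoints, n_perm=49, seed=7)
        assert [(r.entity_label, r.p_value, r.q_value) for r in first.records] == [
            (r.entity_label, r.p_value, r.q_value) for r in second.records
        ]

    def test_zero_variance_entities_dropped_with_warning(self, rng):
        values = rng.standard_normal((3, 6))
        values[1] = 4.0
        entities = _entities(values, labels=["a", "flat", "c"])
        endpoints = _endpoints([rng.standard_normal(6)], ["m"])
        with pytest.warns(UserWarning, match="flat"):
            (result,) = run_endpoint_screen(entities, endpoints, n_perm=19, seed=0)
        assert result.dropped_labels == ["flat"]
        assert [r.entity_label for r in result.records] == ["a", "c"]

    def test_all_null_screen_controls_false_discoveries(self, rng):
        # FDR calibration: iid-noise entities vs an iid-noise endpoint
        n, t, B = 500, 9, 199
        entities = _entities(rng.standard_normal((n, t)))
        endpoints = _endpoints([rng.standard_normal(t)], ["null"])
        (result,) = run_endpoint_screen(entities, endpoints, n_perm=B, seed=3)
        frac = len(result.significant_records) / n
        assert frac <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n)


class TestCorrelateEntities:
    def test_perfect_and_anti_correlation(self):
        base = np.array([1.0, 3.0, 2.0, 5.0, 4.0, 6.0])
        entities = _entities([base, -base], labels=["same", "mirror"])
        records = correlate_entities(entities, TimeSeries("m", base, np.arange(6)))
        by_label = {r.entity_label: r for r in records}
        assert by_label["same"].r == pytest.approx(1.0)
        assert by_label["mirror"].r == pytest.approx(-1.0)
        assert not by_label["mirror"].significant_positive

    def test_r_matches_hand_evaluated_pearson_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        expected = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        (record,) = correlate_entities(_entities([x], labels=["g"]), TimeSeries("m", y, np.arange(4)))
        assert record.r == pytest.approx(expected)

    def test_constant_entity_excluded_with_warning(self, rng):
        values = np.vstack([rng.standard_normal(6), np.full(6, 2.0)])
        entities = _entities(values, labels=["ok", "flat"])
        with pytest.warns(UserWarning, match="flat"):
            records = correlate_entities(entities, TimeSeries("m", rng.standard_normal(6), np.arange(6)))
        assert [r.entity_label for r in records] == ["ok"]


class TestOverlapStats:
    @pytest.mark.parametrize(
        "n_dtw, n_corr, n_overlap, pct_not, pct_found",
        [
            (99, 34, 13, 87, 38),
            (141, 51, 22, 84, 43),
            (102, 53, 18, 82, 34),
            (145, 127, 86, 41, 68),
        ],
    )
    def test_reproduces_printed_comparison_percentages(
        self, n_dtw, n_corr, n_overlap, pct_not, pct_found
    ):
        shared = {f"s{i}" for i in range(n_overlap)}
        dtw = shared | {f"d{i}" for i in range(n_dtw - n_overlap)}
        corr = shared | {f"c{i}" for i in range(n_corr - n_overlap)}
        summary = overlap_stats(dtw, corr)
        assert summary.pct_dtw_not_corr == pct_not
        assert summary.pct_corr_found_by_dtw == pct_found

    def test_zero_denominators_leave_percentages_undefined(self):
        summary = overlap_stats(set(), {"a", "b"})
        assert summary.pct_dtw_not_corr is None
        assert summary.pct_corr_found_by_dtw == 0
        empty = overlap_stats({"a"}, set())
        assert empty.pct_corr_found_by_dtw is None

    def test_overlap_bounded_by_margins(self):
        summary = overlap_stats({"a", "b", "c"}, {"b", "c", "d"})
        assert summary.n_overlap == 2 <= min(summary.n_corr, summary.n_dtw)
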