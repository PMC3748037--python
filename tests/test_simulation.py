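"""Synthetic benchmark: smooth generator, corruption grid, scoring."""

import numpy as np
import pytest

from warpscreen import (
    dtw_align,
    evaluate_benchmark,
    generate_smooth_series,
    intended_path,
    make_benchmark,
    run_matched_screen,
)
from warpscreen.simulation import _smooth_values


class TestGenerateSmoothSeries:
    def test_deterministic_for_a_seed(self):
        first = generate_smooth_series(20, seed=42)
        second = generate_smooth_series(20, seed=42)
        np.testing.assert_array_equal(first.values, second.values)
        assert np.all(np.isfinite(first.values)) and len(first) == 20

    def test_knot_values_reproduced_at_knot_positions(self):
        # 20 points -> 4 knots at positions 1, 20/3+..., evenly spanning [1, 20]
        rng = np.random.default_rng(7)
        n_knots = 4
        positions = np.linspace(1, 20, n_knots)
        knots = np.random.default_rng(7).standard_normal(n_knots)
        values = _smooth_values(20, rng)
        for pos, knot in zip(positions, knots):
            if float(pos).is_integer():
                assert values[int(pos) - 1] == pytest.approx(knot)

    def test_smoother_than_iid_noise(self, rng):
        def lag1(x):
            return np.corrcoef(x[:-1], x[1:])[0, 1]

        smooth = np.mean([lag1(_smooth_values(20, rng)) for _ in range(1000)])
        iid = np.mean([lag1(rng.standard_normal(20)) for _ in range(1000)])
        assert smooth > 0.5 > abs(iid) + 0.4  # iid averages ~0, smooth is high

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            generate_smooth_series(3)


class TestMakeBenchmark:
    def test_default_configuration_shapes(self):
        # full-scale design: 11,000 + 11,000 series of length 20
        bm = make_benchmark(n_matched=100, n_decoys=10, seed=0)
        assert bm.set_a.n == bm.set_b.n == 110
        assert bm.set_a.t == bm.set_b.t == 20
        assert bm.mother_length == 29
        assert len(bm.matched_labels()) == 100
        assert len(bm.decoy_labels()) == 10

    def test_balanced_cells_and_truth_table(self):
        bm = make_benchmark(n_matched=400, n_decoys=40, seed=1)
        matched = bm.truth[bm.truth["matched_index"] >= 0]
        cells = matched.groupby(["shift", "noise_level"]).size()
        assert len(cells) == 100 and set(cells) == {4}
        decoys = bm.truth[bm.truth["matched_index"] < 0]
        assert decoys["shift"].isna().all() and decoys["noise_level"].isna().all()

    def test_zero_corruption_rows_identical_across_sets(self):
        bm = make_benchmark(n_matched=10, n_decoys=0, max_shift=0, n_noise_levels=1, noise_step=0.0, seed=2)
        np.testing.assert_allclose(bm.set_a.values, bm.set_b.values)

    def test_shifted_rows_window_the_same_mother(self):
        bm = make_benchmark(n_matched=100, n_decoys=0, noise_step=0.0, seed=3)
        matched = bm.truth[bm.truth["matched_index"] >= 0]
        for label, row in matched.iterrows():
            k = int(row["shift"])
            i = int(row["matched_index"])
            overlap_a = bm.set_a.values[i, k:]
            overlap_b = bm.set_b.values[i, : 20 - k]
            np.testing.assert_allclose(overlap_a, overlap_b)

    def test_unbalanced_count_truncated_with_warning(self):
        with pytest.warns(UserWarning, match="truncating"):
            bm = make_benchmark(n_matched=105, n_decoys=0, seed=4)
        assert len(bm.matched_labels()) == 100

    def test_reproducible_for_a_seed(self):
        first = make_benchmark(n_matched=100, n_decoys=10, seed=5)
        second = make_benchmark(n_matched=100, n_decoys=10, seed=5)
        np.testing.assert_array_equal(first.set_b.values, second.set_b.values)


class TestIntendedPath:
    def test_zero_shift_is_the_pure_diagonal(self):
        assert intended_path(4, 0).pairs == ((1, 1), (2, 2), (3, 3), (4, 4))

    def test_hand_constructed_shift_two_path(self):
        assert intended_path(5, 2).pairs == (
            (1, 1), (2, 1), (3, 1), (4, 2), (5, 3), (5, 4), (5, 5),
        )

    def test_invalid_shift_rejected(self):
        with pytest.raises(ValueError):
            intended_path(5, 5)

    def test_recovered_by_alignment_on_noiseless_small_shifts(self, rng):
        # small shifts (<= 2): the intended path is the DTW optimum almost
        # always; at larger shifts DTW legitimately finds cheaper paths.
        from warpscreen import TimeSeries

        hits = trials = 0
        for _ in range(300):
            shift = int(rng.integers(0, 3))
            mother = _smooth_values(29, rng)
            a = TimeSeries("a", mother[:20], np.arange(1.0, 21.0))
            b = TimeSeries("b", mother[shift : shift + 20], np.arange(1.0, 21.0))
            result = dtw_align(a, b)
            trials += 1
            hits += result.path.pairs == intended_path(20, shift).pairs
        assert hits / trials >= 0.95


class TestEvaluateBenchmark:
    def test_zero_corruption_cell_scores_100_percent(self):
        bm = make_benchmark(n_matched=10, n_decoys=0, max_shift=0, n_noise_levels=1, noise_step=0.0, seed=6)
        result = run_matched_screen(bm.set_a, bm.set_b, n_perm=199, seed=6)
        grid = evaluate_benchmark(bm, result, fdr=0.05)
        assert grid.detection_pct[0, 0] == 100.0
        assert grid.exact_path_pct[0, 0] == 100.0

    def test_zero_fdr_sentinel_detects_nothing(self):
        bm = make_benchmark(n_matched=100, n_decoys=10, seed=7)
        result = run_matched_screen(bm.set_a, bm.set_b, n_perm=19, seed=7)
        grid = evaluate_benchmark(bm, result, fdr=0.0)
        assert np.all(grid.detection_pct == 0.0)

    def test_label_mismatch_rejected(self):
        bm = make_benchmark(n_matched=100, n_decoys=10, seed=8)
        result = run_matched_screen(bm.set_a, bm.set_b, n_perm=19, seed=8)
        with pytest.raises(ValueError, match="missing"):
            evaluate_benchmark(bm, result.records[:-5], fdr=0.05)

    def test_grids_are_reproducible_for_a_seed(self):
        def run():
            bm = make_benchmark(n_matched=100, n_decoys=10, seed=9)
            result = run_matched_screen(bm.set_a, bm.set_b, n_perm=49, seed=9)
            return evaluate_benchmark(bm, result, fdr=0.05)

        np.testing.assert_array_equal(run().detection_pct, run().detection_pct)
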