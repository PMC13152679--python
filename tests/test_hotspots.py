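"""Grid tiling, the 2-SD active-ROI rule, and condition comparison."""

import numpy as np
import pytest

from dopamap.hotspots import (
    apply_grid,
    compare_conditions,
    detect_active_rois,
    integrated_response,
)
from dopamap.io import MovieStack
from dopamap.preprocessing import BaselineSpec, compute_dff


def brute_force_active(trial_traces, stim_frame, k, window):
    """Independent loop implementation of the activity criterion.

    trial_traces: list of (R, C, T) arrays.  Per square: per-trial baseline
    mean/SD and window peak, averaged across trials, then peak > mean + k*SD.
    """
    n_rows, n_cols, _ = trial_traces[0].shape
    lo, hi = window
    active = np.zeros((n_rows, n_cols), dtype=bool)
    for r in range(n_rows):
        for c in range(n_cols):
            means, sds, peaks = [], [], []
            for tr in trial_traces:
                base = [tr[r, c, f] for f in range(stim_frame)]
                m = sum(base) / len(base)
                var = sum((b - m) ** 2 for b in base) / (len(base) - 1)
                means.append(m)
                sds.append(var**0.5)
                peaks.append(max(tr[r, c, f] for f in range(lo, hi)))
            m = sum(means) / len(means)
            s = sum(sds) / len(sds)
            p = sum(peaks) / len(peaks)
            active[r, c] = p > m + k * s
    return active


def random_movie(rng, t=24, h=16, w=16, stim=8):
    data = rng.uniform(0.5, 1.5, size=(t, h, w))
    # sprinkle responses into a few squares
    for _ in range(rng.integers(0, 5)):
        r, c = rng.integers(0, h // 8), rng.integers(0, w // 8)
        amp = rng.uniform(0.0, 3.0)
        data[stim + 2 : stim + 6, r * 8 : (r + 1) * 8, c * 8 : (c + 1) * 8] += amp
    return MovieStack(data, frame_rate=2.0, stim_frames=(stim,))


class TestApplyGrid:
    def test_square_count_by_integer_division(self):
        movie = MovieStack(np.ones((3, 256, 256)), frame_rate=1.0)
        grid, mask = apply_grid(movie, 8)
        assert (mask.n_rows, mask.n_cols) == (32, 32)
        assert grid.traces.shape == (32, 32, 3)

    def test_uniform_movie_every_square_equals_global_mean(self):
        rng = np.random.default_rng(0)
        frames = rng.uniform(1, 2, size=10)
        movie = MovieStack(np.tile(frames[:, None, None], (1, 16, 16)), 1.0)
        grid, _ = apply_grid(movie, 8)
        for r in range(2):
            for c in range(2):
                np.testing.assert_allclose(grid.traces[r, c], frames)

    def test_partial_edge_squares_discarded(self):
        movie = MovieStack(np.ones((3, 20, 19)), frame_rate=1.0)
        _, mask = apply_grid(movie, 8)
        assert (mask.n_rows, mask.n_cols) == (2, 2)

    def test_single_bright_block_dominates_its_square(self):
        data = np.ones((6, 16, 16))
        data[:, 8:16, 0:8] += np.arange(6)[:, None, None] + 1.0
        grid, _ = apply_grid(MovieStack(data, 1.0), 8)
        for f in range(6):
            frame_vals = grid.traces[:, :, f]
            assert np.argmax(frame_vals) == np.ravel_multi_index((1, 0), (2, 2))


class TestDetectActiveRois:
    def test_all_constant_movie_zero_active(self):
        movie = MovieStack(np.ones((20, 16, 16)), 2.0, stim_frames=(8,))
        grid, _ = apply_grid(movie, 8)
        rmap = detect_active_rois(grid, 8)
        assert rmap.n_active == 0
        assert rmap.degenerate.all()

    def test_agrees_with_brute_force_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(120):
            n_trials = int(rng.integers(1, 4))
            trials = [apply_grid(random_movie(rng), 8)[0] for _ in range(n_trials)]
            k = float(rng.uniform(0.5, 3.0))
            rmap = detect_active_rois(trials, 8, k=k, response_window=(8, 24))
            expected = brute_force_active([t.traces for t in trials], 8, k, (8, 24))
            np.testing.assert_array_equal(rmap.active, expected)

    def test_active_count_monotone_in_k(self):
        rng = np.random.default_rng(7)
        grid, _ = apply_grid(random_movie(rng), 8)
        counts = [detect_active_rois(grid, 8, k=k).n_active for k in (0.5, 1, 2, 3, 5)]
        assert counts == sorted(counts, reverse=True)

    def test_active_set_invariant_under_intensity_rescaling(self):
        rng = np.random.default_rng(3)
        raw = MovieStack(rng.uniform(100, 200, (24, 16, 16)), 2.0, stim_frames=(8,))
        raw.data[10:14, 0:8, 0:8] += 300.0
        spec = BaselineSpec("prestim_mean")
        scaled = MovieStack(raw.data * 4.7, 2.0, stim_frames=(8,))
        a = detect_active_rois(apply_grid(compute_dff(raw, spec), 8)[0], 8)
        b = detect_active_rois(apply_grid(compute_dff(scaled, spec), 8)[0], 8)
        np.testing.assert_array_equal(a.active, b.active)

    def test_fixture_recovers_hotspot_squares_exactly(self, striatal_fixture):
        movies, truth = striatal_fixture
        spec = BaselineSpec("prestim_mean")
        grids = [apply_grid(compute_dff(m, spec), truth["square_px"])[0] for m in movies]
        rmap = detect_active_rois(grids, truth["stim_frame"])
        expected = {tuple(s) for s in truth["hotspot_squares"]}
        assert {tuple(map(int, rc)) for rc in np.argwhere(rmap.active)} == expected


class TestIntegratedResponse:
    def test_uniform_transient_peak(self):
        data = np.zeros((20, 8, 8))
        data[10] = 0.2
        trace, peak = integrated_response(MovieStack(data, 1.0), (5, 15))
        assert peak == pytest.approx(0.2)

    def test_field_mean_equals_mean_of_square_traces(self):
        rng = np.random.default_rng(0)
        movie = MovieStack(rng.uniform(0, 1, (12, 16, 16)), 1.0)
        grid, _ = apply_grid(movie, 8)
        np.testing.assert_allclose(
            grid.traces.mean(axis=(0, 1)), movie.mean_trace().values, rtol=1e-12
        )

    def test_areal_weighting_of_disjoint_hotspots(self):
        data = np.zeros((10, 16, 16))
        data[5, 0:4, 0:4] = 0.8   # area fraction 1/16
        data[5, 8:12, 8:12] = 0.8
        _, peak = integrated_response(MovieStack(data, 1.0), (0, 10))
        assert peak == pytest.approx(2 * (1 / 16) * 0.8)


class TestCompareConditions:
    def _rmap(self, movie, stim=8):
        grid, _ = apply_grid(compute_dff(movie, BaselineSpec("prestim_mean")), 8)
        return detect_active_rois(grid, stim)

    def test_identical_conditions_zero_deltas(self):
        rng = np.random.default_rng(5)
        movie = MovieStack(rng.uniform(100, 110, (24, 16, 16)), 2.0, stim_frames=(8,))
        movie.data[10:12, 0:8, 0:8] += 100
        rmap = self._rmap(movie)
        comp = compare_conditions(rmap, rmap)
        assert comp.delta_percent_active == 0.0
        assert comp.delta_integrated_peak == 0.0

    def test_zero_release_after_gives_full_roi_reduction(self):
        base = np.full((24, 16, 16), 100.0)
        before = MovieStack(base.copy(), 2.0, stim_frames=(8,))
        before.data[10:12, 0:8, 0:8] += 200
        after = MovieStack(base.copy(), 2.0, stim_frames=(8,))
        comp = compare_conditions(self._rmap(before), self._rmap(after))
        assert comp.delta_percent_active == pytest.approx(-1.0)

    def test_swapping_conditions_negates_consistently(self):
        rng = np.random.default_rng(9)
        m1 = MovieStack(rng.uniform(100, 110, (24, 16, 16)), 2.0, stim_frames=(8,))
        m1.data[10:13, 0:8, 0:8] += 80
        m2 = MovieStack(rng.uniform(100, 110, (24, 16, 16)), 2.0, stim_frames=(8,))
        m2.data[10:13, 0:8, 0:8] += 40
        m2.data[10:13, 8:16, 8:16] += 80
        fwd = compare_conditions(self._rmap(m1), self._rmap(m2))
        rev = compare_conditions(self._rmap(m2), self._rmap(m1))
        # fractional changes relative to the first argument: d_rev = -d/(1+d)
        d = fwd.delta_percent_active
        assert rev.delta_percent_active == pytest.approx(-d / (1 + d))

    def test_heatmap_written(self, tmp_path):
        from dopamap.hotspots import save_heatmap

        rng = np.random.default_rng(1)
        m = MovieStack(rng.uniform(100, 110, (24, 16, 16)), 2.0, stim_frames=(8,))
        save_heatmap(self._rmap(m), tmp_path / "hm.png")
        assert (tmp_path / "hm.png").stat().st_size > 0

    def test_grid_mismatch_rejected(self):
        rng = np.random.default_rng(2)
        m1 = MovieStack(rng.uniform(100, 110, (24, 16, 16)), 2.0, stim_frames=(8,))
        m2 = MovieStack(rng.uniform(100, 110, (24, 24, 24)), 2.0, stim_frames=(8,))
        with pytest.raises(ValueError, match="mismatch"):
            compare_conditions(self._rmap(m1), self._rmap(m2))
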