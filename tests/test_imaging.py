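"""ROI detection, flash detection, assignment, evoked classification,
Pr computation and paired pre/post comparison."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from quantal.datatypes import StimProtocol
from quantal.imaging import (PrMap, ROISet, assign_events, classify_evoked,
                             compare_php, compute_pr, detect_optical_events,
                             detect_rois, event_density_rois)
from quantal.synth import (ReleaseModelParams, SyntheticMovieParams,
                           grid_az_positions, simulate_release, synthesize_movie,
                           synthesize_reference_stack)


class TestDetectROIs:
    def test_twenty_spots_recovered_at_snr10(self):
        pos, shape = grid_az_positions(20, spacing=12, margin=10)
        mp = SyntheticMovieParams(az_positions=pos, shape=shape, n_frames=4)
        ref = synthesize_reference_stack(mp, spot_amplitude=100, noise_sigma=10)
        rois = detect_rois(ref)
        assert len(rois) == 20
        d, _ = cKDTree(rois.centers).query(pos)
        assert d.max() <= 1.0

    def test_blank_image_yields_empty_set_with_warning(self):
        blank = 100 + 10 * np.random.default_rng(0).standard_normal((2, 48, 48))
        with pytest.warns(UserWarning, match="no PSD spots"):
            rois = detect_rois(blank.astype(np.float32))
        assert len(rois) == 0

    def test_close_spots_collapse_to_brighter_peak(self):
        img = np.zeros((2, 40, 40), dtype=float)
        yy, xx = np.mgrid[:40, :40]
        g = lambda x0, y0, a: a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / 4.5)
        img[0] = g(15, 20, 80) + g(17, 20, 120) + g(30, 10, 100)
        img[0] += 2 * np.random.default_rng(1).standard_normal((40, 40))
        rois = detect_rois(img)
        assert len(rois) == 2
        d, i = cKDTree(rois.centers).query([[17.0, 20.0]])
        assert d[0] <= 1.5  # the brighter of the merged pair wins

    def test_manual_append_assigns_fresh_unique_id(self):
        rois = ROISet(centers=[[5.0, 5.0]], radius=3.0)
        new_id = rois.append([10.0, 10.0])
        assert new_id == 1 and len(rois) == 2
        with pytest.raises(ValueError):
            rois.append([1.0, 1.0], roi_id=1)


class TestDetectEvents:
    def test_single_flash_found_at_correct_frame_and_position(self):
        params = ReleaseModelParams(n_az=1, p_v=1.0, rho=1.0, mini_rate=0.0,
                                    f_async=0.0, sync_sigma=0.0, seed=3)
        prot = StimProtocol.periodic(1, 0.3, start=2.0)
        rec = simulate_release(params, prot)
        mp = SyntheticMovieParams(az_positions=[[15.0, 9.0]], shape=(24, 32),
                                  n_frames=160, noise_sigma=5.0)
        stack, truth = synthesize_movie(rec, mp)
        events = detect_optical_events(stack)
        assert len(events) == 1
        assert int(events["frame"].iloc[0]) == int(truth["frame"].iloc[0])
        assert np.hypot(events["x_px"].iloc[0] - 15, events["y_px"].iloc[0] - 9) < 1.0

    def test_noise_only_movie_false_events_below_percent_of_frames(self):
        rng = np.random.default_rng(11)
        movie = (100 + 10 * rng.standard_normal((600, 48, 52))).astype(np.float32)
        events = detect_optical_events(movie)
        frames_with_events = len(set(events["frame"])) if len(events) else 0
        assert frames_with_events / 600 < 0.01

    def test_baseline_window_longer_than_movie_rejected(self):
        movie = np.zeros((50, 16, 16), dtype=np.float32)
        with pytest.raises(ValueError, match="baseline"):
            detect_optical_events(movie)


class TestAssignment:
    def _rois(self):
        return ROISet(centers=[[10.0, 10.0], [20.0, 10.0]], radius=3.0)

    def test_event_at_center_assigned(self):
        ev = pd.DataFrame({"frame": [0], "x_px": [10.0], "y_px": [10.0],
                           "peak_df": [5.0], "peak_dff": [0.05]})
        out = assign_events(ev, self._rois())
        assert out["assigned_roi"].iloc[0] == 0

    def test_equidistant_tie_goes_to_lower_id(self):
        ev = pd.DataFrame({"frame": [0], "x_px": [15.0], "y_px": [10.0],
                           "peak_df": [5.0], "peak_dff": [0.05]})
        out = assign_events(ev, self._rois())
        assert out["assigned_roi"].iloc[0] == 0

    def test_distant_event_reported_unassigned(self):
        ev = pd.DataFrame({"frame": [0], "x_px": [40.0], "y_px": [40.0],
                           "peak_df": [5.0], "peak_dff": [0.05]})
        out = assign_events(ev, self._rois())
        assert out["assigned_roi"].iloc[0] == -1
        assert np.isfinite(out["assign_dist"].iloc[0])


class TestClassifyEvoked:
    def _events(self, frames):
        return pd.DataFrame({"frame": frames,
                             "x_px": np.zeros(len(frames)),
                             "y_px": np.zeros(len(frames)),
                             "peak_df": np.ones(len(frames)),
                             "peak_dff": np.ones(len(frames))})

    def test_two_simultaneous_events_not_evoked(self):
        ev, frames = classify_evoked(self._events([5, 5]), 10)
        assert frames.size == 0 and not ev["evoked"].any()

    def test_three_simultaneous_events_evoked(self):
        ev, frames = classify_evoked(self._events([5, 5, 5, 7]), 10)
        assert list(frames) == [5]
        assert ev["evoked"].tolist() == [True, True, True, False]

    def test_stim_times_mode_flags_stimulus_frames(self):
        prot = StimProtocol.periodic(3, 0.5, start=1.0)
        ev, frames = classify_evoked(self._events([8, 24, 40, 3]), 50,
                                     mode="stim_times", protocol=prot,
                                     frame_rate=8.0)
        assert set(frames) == {8, 24, 40}
        assert ev["evoked"].tolist() == [True, True, True, False]


class TestPrMap:
    def _pr_map(self, pr_values, n_stims=54):
        table = pd.DataFrame({"roi_id": np.arange(len(pr_values)),
                              "n_evoked": np.round(np.array(pr_values) * n_stims),
                              "pr": pr_values})
        return PrMap(table=table, n_stims=n_stims)

    def test_pr_is_events_over_stimulations(self):
        rois = ROISet(centers=[[5.0, 5.0], [15.0, 5.0]], radius=3.0)
        ev = pd.DataFrame({"frame": np.arange(5), "x_px": [5.0] * 5,
                           "y_px": [5.0] * 5, "peak_df": [5.0] * 5,
                           "peak_dff": [0.05] * 5,
                           "assigned_roi": [0] * 5,
                           "evoked": [True] * 5})
        prm = compute_pr(ev, rois, 54)
        assert prm.table.loc[0, "pr"] == pytest.approx(5 / 54)
        assert prm.table.loc[1, "pr"] == 0.0 and prm.n_silent == 1

    def test_event_counts_conserved(self):
        rois = ROISet(centers=[[5.0, 5.0]], radius=3.0)
        ev = pd.DataFrame({"frame": [0, 0, 0], "x_px": [5.0, 5.0, 40.0],
                           "y_px": [5.0, 5.0, 40.0], "peak_df": [5.0] * 3,
                           "peak_dff": [0.05] * 3})
        ev = assign_events(ev, rois)
        ev["evoked"] = True
        prm = compute_pr(ev, rois, 10)
        assert prm.table["n_evoked"].sum() + prm.unassigned_evoked == 3

    def test_zero_stims_rejected(self):
        with pytest.raises(ValueError):
            compute_pr(pd.DataFrame(), ROISet(centers=[[1.0, 1.0]], radius=3), 0)

    def test_pr_times_n_stims_is_integral(self):
        prm = self._pr_map([5 / 54, 0.0, 11 / 54])
        prod = prm.table["pr"] * prm.n_stims
        assert np.allclose(prod, np.round(prod))


class TestComparePHP:
    def _map_from(self, prs, n_stims=200):
        t = pd.DataFrame({"roi_id": np.arange(len(prs)),
                          "n_evoked": np.round(np.array(prs) * n_stims),
                          "pr": prs})
        return PrMap(table=t, n_stims=n_stims)

    def test_identical_maps_give_unit_fold_and_no_recruitment(self):
        m = self._map_from([0.1, 0.2, 0.0, 0.3])
        cmp_res = compare_php(m, m)
        assert cmp_res.fold_change == pytest.approx(1.0)
        assert cmp_res.recruited == 0

    def test_recruited_counts_silent_to_active(self):
        pre = self._map_from([0.0] * 10 + [0.2] * 5)
        post_pr = [0.1] * 4 + [0.0] * 6 + [0.2] * 5
        post = self._map_from(post_pr)
        cmp_res = compare_php(pre, post)
        assert cmp_res.recruited == 4

    def test_incomplete_correspondence_counted(self):
        pre = self._map_from([0.1, 0.2, 0.3])
        post = self._map_from([0.1, 0.2])
        cmp_res = compare_php(pre, post, correspondence={0: 0, 1: 1, 2: 99})
        assert cmp_res.n_unmatched == 1
        assert len(cmp_res.per_roi) == 2

    def test_binomial_resampled_fold_change_recovers_potentiation(self):
        # pre/post sessions resampled at 200 stimuli with Pr scaled by 1.8
        rng = np.random.default_rng(23)
        folds = []
        for _ in range(50):
            true_pr = rng.beta(2, 10, size=150) * 0.5
            pre = self._map_from(rng.binomial(200, true_pr) / 200)
            post = self._map_from(rng.binomial(200, np.clip(1.8 * true_pr, 0, 1)) / 200)
            folds.append(compare_php(pre, post).fold_change)
        assert 1.6 <= np.mean(folds) <= 2.0


def test_event_density_rois_recover_active_sites():
    rng = np.random.default_rng(5)
    centers = np.array([[10.0, 10.0], [25.0, 12.0], [14.0, 30.0]])
    events = pd.DataFrame({
        "frame": np.arange(300),
        "x_px": np.concatenate([c[0] + 0.6 * rng.standard_normal(100) for c in centers]),
        "y_px": np.concatenate([c[1] + 0.6 * rng.standard_normal(100) for c in centers]),
        "peak_df": np.ones(300), "peak_dff": np.ones(300)})
    rois = event_density_rois(events, (40, 40))
    assert len(rois) == 3
    d, _ = cKDTree(rois.centers).query(centers)
    assert d.max() <= 1.5
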