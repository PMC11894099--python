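"""Squeezing events, track summaries, correlations and the SF heatmap."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nucleodyn.dynamics import (
    correlation_matrix,
    detect_squeezing,
    sf_heatmap,
    summarize_track,
    summarize_tracks,
)


def rle_oracle(series, threshold):
    """Independent run-length-encoding event finder (plain loop)."""
    events = []
    run = None
    for i, v in enumerate(series):
        above = (not math.isnan(v)) and v >= threshold
        if above and run is None:
            run = [i, i]
        elif above:
            run[1] = i
        elif run is not None:
            events.append(tuple(run))
            run = None
    if run is not None:
        events.append(tuple(run))
    return events


def make_track(points, frame_interval_s=30.0, sf=None, frames=None):
    xs, ys = zip(*points)
    n = len(xs)
    return pd.DataFrame(
        dict(
            track_id=0,
            frame=frames if frames is not None else range(n),
            x_um=xs,
            y_um=ys,
            sf=sf if sf is not None else [0.1] * n,
        )
    )


class TestDetectSqueezing:
    def test_worked_example(self):
        events, prop = detect_squeezing([0.2, 0.5, 0.6, 0.3, 0.45], 0.4, 30.0)
        assert [(e.start_frame, e.end_frame) for e in events] == [(1, 2), (4, 4)]
        assert sorted(e.n_frames for e in events) == [1, 2]
        assert prop == pytest.approx(3 / 5)

    def test_no_events_below_threshold(self):
        events, prop = detect_squeezing([0.1, 0.2, 0.39], 0.4)
        assert events == [] and prop == 0.0

    def test_threshold_is_inclusive(self):
        events, prop = detect_squeezing([0.1, 0.40, 0.1], 0.4)
        assert len(events) == 1 and prop == pytest.approx(1 / 3)

    def test_gaps_break_runs_and_denominator(self):
        series = [0.5, np.nan, 0.5, 0.5]
        events, prop = detect_squeezing(series, 0.4)
        assert [(e.start_frame, e.end_frame) for e in events] == [(0, 0), (2, 3)]
        assert prop == pytest.approx(1.0)  # 3 squeezing / 3 observed

    def test_duration_units(self):
        events, _ = detect_squeezing([0.5, 0.5, 0.1], 0.4, frame_interval_s=30.0)
        assert events[0].duration_min == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            detect_squeezing([], 0.4)
        with pytest.raises(ValueError):
            detect_squeezing([0.5], 1.5)

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(
            st.one_of(st.floats(0, 0.999), st.just(float("nan"))),
            min_size=1,
            max_size=60,
        )
    )
    def test_matches_rle_oracle(self, series):
        events, prop = detect_squeezing(series, 0.4)
        assert [(e.start_frame, e.end_frame) for e in events] == rle_oracle(series, 0.4)
        n_obs = sum(not math.isnan(v) for v in series)
        n_sq = sum((not math.isnan(v)) and v >= 0.4 for v in series)
        if n_obs:
            assert prop == pytest.approx(n_sq / n_obs)


class TestSummarizeTrack:
    def test_straight_line_persistence_is_one(self):
        pts = [(i * 2.0, 0.0) for i in range(31)]
        s = summarize_track(make_track(pts), 30.0)
        assert s.persistence == pytest.approx(1.0)
        assert s.mean_speed_um_min == pytest.approx(4.0)
        assert not s.window_rescaled

    def test_hand_summed_polyline(self):
        # (0,0)->(1,0)->(1,1): path 2, euclidean sqrt(2); 1-min track rescaled
        s = summarize_track(make_track([(0, 0), (1, 0), (1, 1)]), 30.0)
        assert s.window_rescaled
        scale = 15.0  # 15 min / 1 min observed
        assert s.path_length_um == pytest.approx(2.0 * scale)
        assert s.euclidean_um == pytest.approx(math.sqrt(2) * scale)
        assert s.persistence == pytest.approx(math.sqrt(2) / 2)

    def test_stationary_track_excluded_persistence(self):
        s = summarize_track(make_track([(1.0, 1.0)] * 5), 30.0)
        assert s.mean_speed_um_min == 0.0
        assert math.isnan(s.persistence)

    def test_truncation_to_window(self):
        # 40 frames at 30 s = 19.5 min; window covers frames 0..30
        pts = [(i * 1.0, 0.0) for i in range(40)]
        s = summarize_track(make_track(pts), 30.0)
        assert s.path_length_um == pytest.approx(30.0)
        assert s.euclidean_um == pytest.approx(30.0)
        assert not s.window_rescaled

    def test_euclidean_never_exceeds_path(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pts = rng.normal(size=(15, 2)).cumsum(axis=0)
            s = summarize_track(make_track([tuple(p) for p in pts]), 30.0)
            assert s.euclidean_um <= s.path_length_um + 1e-9

    def test_sf_statistics_and_events(self):
        sf = [0.1, 0.5, 0.5, 0.2, 0.45]
        s = summarize_track(make_track([(i, 0) for i in range(5)], sf=sf), 30.0)
        assert s.mean_sf == pytest.approx(np.mean(sf))
        assert s.max_sf == pytest.approx(0.5)
        assert s.n_events == 2
        assert s.squeeze_proportion == pytest.approx(3 / 5)
        assert s.mean_event_duration_min == pytest.approx((2 * 0.5 + 1 * 0.5) / 2)


class TestCorrelationMatrix:
    def test_perfect_linear(self):
        df = pd.DataFrame(dict(a=np.arange(10.0), b=2 * np.arange(10.0)))
        for method in ("pearson", "spearman"):
            cm = correlation_matrix(df, ["a", "b"], method)
            assert cm.r.loc["a", "b"] == pytest.approx(1.0)

    def test_hand_computed_spearman(self):
        # d = (1,1,1,1) -> rho = 1 - 6*4/(4*15) = 0.6
        df = pd.DataFrame(dict(x=[1, 2, 3, 4], y=[2, 1, 4, 3]))
        cm = correlation_matrix(df, ["x", "y"], "spearman")
        assert cm.r.loc["x", "y"] == pytest.approx(0.6)

    def test_antisymmetry_and_diagonal(self):
        x = np.arange(8.0)
        df = pd.DataFrame(dict(x=x, y=-x, z=x**2))
        cm = correlation_matrix(df, ["x", "y", "z"], "pearson")
        assert cm.r.loc["x", "y"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(cm.r.to_numpy()), 1.0)
        assert np.allclose(cm.r.to_numpy(), cm.r.to_numpy().T)

    def test_zero_variance_warns_nan(self):
        df = pd.DataFrame(dict(a=np.arange(5.0), b=np.ones(5)))
        with pytest.warns(UserWarning, match="zero variance"):
            cm = correlation_matrix(df, ["a", "b"], "pearson")
        assert math.isnan(cm.r.loc["a", "b"])

    def test_too_few_records_rejected(self):
        df = pd.DataFrame(dict(a=[1.0, 2.0], b=[1.0, 2.0]))
        with pytest.raises(ValueError):
            correlation_matrix(df, ["a", "b"], "pearson")


class TestHeatmap:
    def make_tracks(self, xs_px, ys_px, sf, pixel_size=0.3):
        return pd.DataFrame(
            dict(
                track_id=0,
                frame=range(len(xs_px)),
                x_um=np.asarray(xs_px) * pixel_size,
                y_um=np.asarray(ys_px) * pixel_size,
                sf=sf,
            )
        )

    def test_single_bin(self):
        df = self.make_tracks([1, 2, 3], [1, 2, 3], [0.1, 0.2, 0.6])
        grid = sf_heatmap(df, 17, (34, 34), 0.3)
        assert grid.mean_sf[0, 0] == pytest.approx(0.3)
        assert np.isnan(grid.mean_sf[0, 1]) and np.isnan(grid.mean_sf[1, 1])
        assert grid.counts.sum() == 3

    def test_count_weighted_mean_conservation(self):
        rng = np.random.default_rng(3)
        df = self.make_tracks(
            rng.uniform(0, 100, 500), rng.uniform(0, 60, 500), rng.uniform(0, 1, 500)
        )
        grid = sf_heatmap(df, 17, (60, 100), 0.3)
        weighted = np.nansum(grid.mean_sf * grid.counts) / grid.counts.sum()
        assert weighted == pytest.approx(df.sf.mean(), abs=1e-9)

    def test_boundary_goes_to_higher_bin(self):
        df = self.make_tracks([17.0], [0.0], [0.5])
        grid = sf_heatmap(df, 17, (34, 51), 0.3)
        assert grid.counts[0, 1] == 1 and grid.counts[0, 0] == 0

    def test_outside_field_clipped_with_warning(self):
        df = self.make_tracks([999.0], [0.0], [0.5])
        with pytest.warns(UserWarning, match="clipped"):
            grid = sf_heatmap(df, 17, (34, 34), 0.3)
        assert grid.counts[0, -1] == 1


def test_summarize_tracks_one_row_per_track():
    frames = list(range(6))
    df = pd.concat(
        [
            pd.DataFrame(
                dict(track_id=tid, frame=frames, x_um=np.arange(6.0) * tid,
                     y_um=0.0, sf=0.1)
            )
            for tid in (1, 2, 3)
        ]
    )
    out = summarize_tracks(df, 30.0)
    assert list(out["track_id"]) == [1, 2, 3]
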