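import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eyefatigue.errors import ValidationError
from eyefatigue.gaze_features import (
    DetectorConfig,
    Fixation,
    detect_blinks,
    detect_fixations,
    extract_feature_vector,
    scanpath_metrics,
    unify_feature_table,
    unify_features,
)
from eyefatigue.synthetic_data import GazeStream

from .helpers import oracle_blinks, oracle_fixations, random_gaze_arrays


def stream_from(x, y, valid=None, rate=75.0):
    x = np.asarray(x, dtype=float)
    valid = np.ones(len(x), dtype=bool) if valid is None else np.asarray(valid, dtype=bool)
    return GazeStream(t=np.arange(len(x)) / rate, x=x, y=np.asarray(y, dtype=float), valid=valid)


class TestDetectFixations:
    def test_stationary_stream_single_fixation(self):
        s = stream_from(np.full(1500, 500.0), np.full(1500, 600.0))
        fx = detect_fixations(s)
        assert len(fx) == 1
        assert fx[0].duration == pytest.approx(20.0)
        assert (fx[0].centroid_x, fx[0].centroid_y) == (500.0, 600.0)

    def test_two_clusters_two_fixations(self, rng):
        x = np.concatenate([100 + rng.uniform(-1, 1, 75), 600 + rng.uniform(-1, 1, 75)])
        y = np.concatenate([100 + rng.uniform(-1, 1, 75), 600 + rng.uniform(-1, 1, 75)])
        s = stream_from(x, y)
        fx = detect_fixations(s)
        assert len(fx) == 2
        assert fx[0].centroid_x == pytest.approx(100, abs=1)
        assert fx[1].centroid_x == pytest.approx(600, abs=1)
        got = [(f.start, f.n_samples) for f in fx]
        expected = oracle_fixations(s.t, s.x, s.y, s.valid, 0.2, 10.0)
        assert got == [(s.t[i], j - i + 1) for i, j in expected]

    def test_short_dwell_below_minimum_ignored(self, rng):
        # a 0.15-s dwell (11 samples at 75 Hz) between large moves: no fixation
        moving_x = np.concatenate(
            [
                np.linspace(0, 800, 30),
                500 + rng.uniform(-1, 1, 11),
                np.linspace(800, 0, 30),
            ]
        )
        s = stream_from(moving_x, moving_x)
        assert detect_fixations(s) == []

    def test_invalid_sample_terminates_window(self):
        x = np.full(60, 300.0)
        valid = np.ones(60, dtype=bool)
        valid[30] = False
        s = stream_from(x, x, valid)
        fx = detect_fixations(s)
        assert len(fx) == 2
        assert [f.n_samples for f in fx] == [30, 29]

    def test_non_monotone_timestamps_rejected(self):
        s = GazeStream(t=np.array([0.0, 0.1, 0.05]), x=np.zeros(3), y=np.zeros(3), valid=np.ones(3, bool))
        with pytest.raises(ValidationError):
            detect_fixations(s)

    def test_empty_stream_empty_list(self):
        s = GazeStream(t=np.array([]), x=np.array([]), y=np.array([]), valid=np.array([], bool))
        assert detect_fixations(s) == []

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(30, 300))
    def test_oracle_equivalence_random_streams(self, seed, n):
        rng = np.random.default_rng(seed)
        t, x, y, valid = random_gaze_arrays(rng, n)
        s = GazeStream(t=t, x=x, y=y, valid=valid)
        got = [(f.start, f.n_samples) for f in detect_fixations(s)]
        expected = [(t[i], j - i + 1) for i, j in oracle_fixations(t, x, y, valid, 0.2, 10.0)]
        assert got == expected


class TestDetectBlinks:
    def test_fully_valid_no_blinks(self):
        s = stream_from(np.zeros(100), np.zeros(100))
        assert detect_blinks(s) == []

    def test_fifteen_invalid_samples_is_200ms(self):
        valid = np.ones(100, dtype=bool)
        valid[40:55] = False
        s = stream_from(np.zeros(100), np.zeros(100), valid)
        blinks = detect_blinks(s)
        assert len(blinks) == 1
        assert blinks[0].duration == pytest.approx(15 / 75)

    def test_runs_separated_by_one_valid_sample_are_two_blinks(self):
        valid = np.ones(50, dtype=bool)
        valid[10:14] = False
        valid[15:20] = False
        s = stream_from(np.zeros(50), np.zeros(50), valid)
        assert len(detect_blinks(s)) == 2

    def test_min_blink_samples_filters_single_dropouts(self):
        valid = np.ones(50, dtype=bool)
        valid[10] = False
        valid[20:25] = False
        s = stream_from(np.zeros(50), np.zeros(50), valid)
        assert len(detect_blinks(s)) == 2
        assert len(detect_blinks(s, min_blink_samples=2)) == 1

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000), st.integers(10, 200))
    def test_blink_oracle_equivalence(self, seed, n):
        rng = np.random.default_rng(seed)
        t, x, y, valid = random_gaze_arrays(rng, n)
        s = GazeStream(t=t, x=x, y=y, valid=valid)
        got = [(b.start, b.n_samples) for b in detect_blinks(s)]
        expected = [(t[a], b - a + 1) for a, b in oracle_blinks(valid)]
        assert got == expected


class TestScanpath:
    def fx(self, cx, cy):
        return Fixation(start=0, end=1, duration=1, centroid_x=cx, centroid_y=cy, n_samples=75)

    def test_single_fixation_zero(self):
        assert scanpath_metrics([self.fx(5, 5)]) == {"SL": 0.0, "ML": 0.0}

    def test_three_four_five_triangle(self):
        m = scanpath_metrics([self.fx(0, 0), self.fx(3, 4)])
        assert m["SL"] == pytest.approx(5.0)
        assert m["ML"] == pytest.approx(5.0)

    def test_two_saccades(self):
        m = scanpath_metrics([self.fx(0, 0), self.fx(3, 4), self.fx(3, 0)])
        assert m["SL"] == pytest.approx(9.0)
        assert m["ML"] == pytest.approx(4.5)


class TestFeatureVector:
    def test_stationary_window(self):
        s = stream_from(np.full(1500, 400.0), np.full(1500, 400.0))
        fv = extract_feature_vector(s)
        assert fv.NF == 1
        assert fv.DF == pytest.approx(20.0)
        assert fv.MF == pytest.approx(20.0)
        assert fv.VF == 0.0
        assert (fv.BT, fv.DB, fv.MB, fv.VB, fv.SL, fv.ML) == (0, 0, 0, 0, 0, 0)

    def test_mf_is_df_over_nf(self, small_cohort):
        for stream in list(small_cohort.gaze.values())[:8]:
            fv = extract_feature_vector(stream)
            if fv.NF > 0:
                assert fv.MF == pytest.approx(fv.DF / fv.NF, abs=1e-9)

    def test_conservation_df_plus_db(self, small_cohort):
        for stream in small_cohort.gaze.values():
            fv = extract_feature_vector(stream)
            assert fv.DF + fv.DB <= 20.0 + 1 / 75 + 1e-9

    def test_translation_invariance(self, small_cohort):
        stream = small_cohort.gaze[(1, 2)]
        shifted = GazeStream(
            t=stream.t, x=stream.x + 55.0, y=stream.y - 31.0, valid=stream.valid
        )
        a = extract_feature_vector(stream).as_array()
        b = extract_feature_vector(shifted).as_array()
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_scale_doubles_pixel_features(self, small_cohort):
        stream = small_cohort.gaze[(2, 3)]
        cfg = DetectorConfig()
        scaled = GazeStream(t=stream.t, x=stream.x * 2, y=stream.y * 2, valid=stream.valid)
        # dispersion threshold scaled too, so segmentation is unchanged
        cfg2 = DetectorConfig(px_per_deg=cfg.px_per_deg * 2)
        a = extract_feature_vector(stream, cfg)
        b = extract_feature_vector(scaled, cfg2)
        assert b.NF == a.NF
        assert b.SL == pytest.approx(2 * a.SL, rel=1e-9)
        assert b.ML == pytest.approx(2 * a.ML, rel=1e-9)

    def test_longer_stream_truncated_to_window(self):
        x = np.full(3000, 100.0)
        s = stream_from(x, x)
        fv = extract_feature_vector(s, DetectorConfig(window_s=20.0))
        assert fv.DF == pytest.approx(20.0)

    def test_variance_is_population_variance(self):
        # two fixations of 1 s and 3 s separated by a large jump
        x = np.concatenate([np.full(75, 0.0), np.full(225, 500.0)])
        s = stream_from(x, x)
        fv = extract_feature_vector(s, DetectorConfig(window_s=4.0))
        assert fv.NF == 2
        assert fv.VF == pytest.approx(np.var([1.0, 3.0]))
        assert fv.sd_fixation() == pytest.approx(1.0)


class TestUnifyFeatures:
    def test_epoch1_vector_becomes_zero(self, small_cohort):
        vs = [extract_feature_vector(small_cohort.gaze[(3, e)]) for e in (1, 2, 3, 4)]
        out = unify_features(vs)
        np.testing.assert_allclose(out[0].as_array(), 0.0)

    def test_componentwise_subtraction(self):
        from eyefatigue.gaze_features import FeatureVector

        a = FeatureVector(43, 17, 0.4, 0.1, 2, 0.5, 0.2, 0.0, 6000, 137)
        b = FeatureVector(30, 16, 0.6, 0.9, 10, 2.5, 0.25, 0.01, 16000, 619)
        out = unify_features([a, b])
        np.testing.assert_allclose(out[1].as_array(), b.as_array() - a.as_array())

    def test_nf_series_subtraction(self):
        from eyefatigue.gaze_features import FeatureVector

        vs = [FeatureVector(n, 0, 0, 0, 0, 0, 0, 0, 0, 0) for n in (43, 39, 35, 30)]
        out = unify_features(vs)
        assert [v.NF for v in out] == [0, -4, -8, -13]

    def test_unify_idempotent_after_first_application(self, small_cohort):
        vs = [extract_feature_vector(small_cohort.gaze[(4, e)]) for e in (1, 2, 3, 4)]
        once = unify_features(vs)
        twice = unify_features(once)
        for u, v in zip(once, twice):
            np.testing.assert_allclose(u.as_array(), v.as_array())

    def test_table_unification(self, small_cohort):
        from eyefatigue.gaze_features import extract_cohort_features

        feats = extract_cohort_features(small_cohort.gaze)
        uni = unify_feature_table(feats)
        e1 = uni[uni.epoch == 1]
        assert np.allclose(e1[["NF", "SL", "MB"]].to_numpy(), 0.0)

    def test_missing_baseline_raises(self, small_cohort):
        from eyefatigue.errors import BaselineMissingError
        from eyefatigue.gaze_features import extract_cohort_features

        feats = extract_cohort_features(small_cohort.gaze)
        with pytest.raises(BaselineMissingError):
            unify_feature_table(feats[feats.epoch > 1])
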