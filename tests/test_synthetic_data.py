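import numpy as np
import pytest

from arousalkit.types import ModelParams, VocalEvent
from arousalkit import synthetic_data as sd
from arousalkit.preprocessing import window_heart_rate


class TestSimulateArousalSeries:
    def test_full_one_step_reversion(self):
        p = ModelParams(beta_pos=1.0, beta_neg=1.0, mu=0.0, sigma=0.0)
        s = sd.simulate_arousal_series(p, 5, theta0=2.0, seed=0)
        np.testing.assert_allclose(s.values, [2.0, 0.0, 0.0, 0.0, 0.0])

    def test_no_dynamics_constant(self):
        p = ModelParams(beta_pos=0.0, beta_neg=0.0, mu=0.0, sigma=0.0)
        s = sd.simulate_arousal_series(p, 10, theta0=0.7, seed=0)
        np.testing.assert_allclose(s.values, 0.7)

    def test_stationary_variance_closed_form(self, long_symmetric_series):
        # AR(1) with coefficient (1 - beta): var = sigma^2 / (1 - (1-beta)^2)
        target = 1.0 / (1.0 - 0.25)
        assert np.var(long_symmetric_series.values) == pytest.approx(target, rel=0.05)

    def test_lag1_autocorrelation_matches_ar1(self, long_symmetric_series):
        x = long_symmetric_series.values
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(0.5, abs=0.02)

    def test_deterministic_given_seed(self, symmetric_params):
        a = sd.simulate_arousal_series(symmetric_params, 100, seed=3)
        b = sd.simulate_arousal_series(symmetric_params, 100, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_sign_symmetry(self):
        # negating (series - mu) of (a, b) is distribution-equal to (b, a)
        pa = ModelParams(beta_pos=0.7, beta_neg=0.2, mu=0.0, sigma=1.0)
        pb = ModelParams(beta_pos=0.2, beta_neg=0.7, mu=0.0, sigma=1.0)
        xa = -sd.simulate_arousal_batch(pa, 2000, 200, rng=np.random.default_rng(1))[:, 500:]
        xb = sd.simulate_arousal_batch(pb, 2000, 200, rng=np.random.default_rng(2))[:, 500:]
        assert np.mean(xa) == pytest.approx(np.mean(xb), abs=0.05)
        assert np.var(xa) == pytest.approx(np.var(xb), rel=0.1)
        from scipy.stats import skew
        assert skew(xa.ravel()) == pytest.approx(skew(xb.ravel()), abs=0.1)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(beta_pos=float("nan"), beta_neg=0.5)
        with pytest.raises(ValueError):
            ModelParams(beta_pos=1.5, beta_neg=0.5)
        with pytest.raises(ValueError):
            ModelParams(beta_pos=0.5, beta_neg=0.5, sigma=-1.0)

    def test_n_epochs_must_be_positive(self, symmetric_params):
        with pytest.raises(ValueError):
            sd.simulate_arousal_series(symmetric_params, 0)


class TestSimulateVocalEvents:
    def _series(self, values, pid="p"):
        from arousalkit.types import ArousalSeries
        values = np.asarray(values, dtype=float)
        return ArousalSeries(pid, 0.0, 60.0, values, np.ones(values.size, bool))

    def test_zero_rates_give_no_events(self, rng):
        s = self._series(rng.standard_normal(100))
        events = sd.simulate_vocal_events(s, "high_sr", {"cry": 0, "speech_like": 0})
        assert events == []

    def test_constant_arousal_still_produces_events(self):
        s = self._series(np.zeros(2000))
        events = sd.simulate_vocal_events(s, "low_sr", {"cry": 0.1, "speech_like": 0.0}, seed=1)
        assert len(events) > 100  # no gradient: uniform base rate applies

    def test_unknown_profile(self, rng):
        s = self._series(rng.standard_normal(10))
        with pytest.raises(ValueError, match="profile"):
            sd.simulate_vocal_events(s, "medium_sr")

    def test_cry_likelihood_rises_with_decile(self, rng):
        s = self._series(rng.standard_normal(10_000))
        events = sd.simulate_vocal_events(s, "high_sr", {"cry": 0.1, "speech_like": 0}, seed=5)
        epochs = np.array([int(e.time_s // 60) for e in events])
        order = np.argsort(np.argsort(s.values, kind="stable"))
        decile = (order * 10) // s.values.size
        top = np.sum(decile[epochs] == 9)
        bottom = np.sum(decile[epochs] == 0)
        assert top > bottom

    def test_events_fall_inside_audio_windows(self, rng):
        s = self._series(rng.standard_normal(500))
        events = sd.simulate_vocal_events(s, "high_sr", {"cry": 0.2, "speech_like": 0.2}, seed=2)
        assert events
        for e in events:
            within = e.time_s - 60.0 * int(e.time_s // 60)
            assert 0.0 <= within < sd.AUDIO_SNAPSHOT_S


class TestSimulateDayRecording:
    def test_masks_flag_sleep_and_away(self, small_recording):
        rec = small_recording
        t = rec.arousal.times
        nap = (t >= 7200) & (t < 9600)
        assert not rec.awake_mask[nap].any()
        assert rec.awake_mask[~nap].all()

    def test_audio_windows_cover_5_of_60_awake_home(self, small_recording):
        rec = small_recording
        usable = rec.home_mask & rec.awake_mask
        total = np.sum([w1 - w0 for w0, w1 in rec.audio_sample_windows])
        assert total == pytest.approx(usable.sum() * 60.0 * 5.0 / 60.0)

    def test_heart_rate_tracks_latent_arousal(self, small_recording):
        rec = small_recording
        hr, valid = window_heart_rate(rec.beat_times_s, rec.rr_ms, 60.0,
                                      duration_s=len(rec.arousal) * 60.0)
        latent = rec.arousal.values[: hr.size]
        hi = latent > np.median(latent)
        assert np.nanmean(hr[hi]) > np.nanmean(hr[~hi])

    def test_all_events_inside_windows(self, small_recording):
        rec = small_recording
        starts = np.array([w[0] for w in rec.audio_sample_windows])
        for e in rec.infant_events + rec.adult_events:
            k = np.searchsorted(starts, e.time_s, side="right") - 1
            assert starts[k] <= e.time_s < starts[k] + sd.AUDIO_SNAPSHOT_S

    def test_byte_identical_given_seed(self, asymmetric_params, tmp_path):
        masks = sd.MasksConfig(duration_s=1800.0)
        outs = []
        for run in range(2):
            rec = sd.simulate_day_recording(asymmetric_params, masks, seed=9)
            sf = sd.simulate_stillface_session("low_sr", seed=9)
            d = tmp_path / f"run{run}"
            sd.write_cohort_csvs({"p": rec}, {"p": sf}, str(d))
            outs.append({f.name: f.read_bytes() for f in d.iterdir()})
        assert outs[0] == outs[1]

    def test_too_short_recording(self, asymmetric_params):
        with pytest.raises(ValueError, match="shorter"):
            sd.simulate_day_recording(
                asymmetric_params, sd.MasksConfig(duration_s=10.0), seed=0
            )


class TestStillFace:
    def test_zero_rate_zero_counts(self):
        rec = sd.simulate_stillface_session(
            "low_sr", seed=0, behavior_rate_still=0.0, affect_coupling=0.0
        )
        assert rec.behavior_count[rec.phase == "still"].sum() == 0

    def test_group_separation_in_expectation(self):
        from arousalkit.stillface_lab import self_regulation_score
        lows, highs = [], []
        for seed in range(120):
            lows.append(self_regulation_score(sd.simulate_stillface_session("low_sr", seed)))
            highs.append(self_regulation_score(sd.simulate_stillface_session("high_sr", 1000 + seed)))
        assert np.mean(highs) > np.mean(lows)

    def test_high_sr_less_negative_affect_during_still(self):
        lows, highs = [], []
        for seed in range(60):
            lo = sd.simulate_stillface_session("low_sr", seed)
            hi = sd.simulate_stillface_session("high_sr", 1000 + seed)
            lows.append(lo.affect[lo.phase == "still"].mean())
            highs.append(hi.affect[hi.phase == "still"].mean())
        assert np.mean(highs) > np.mean(lows)

    def test_fixed_seed_identical(self):
        a = sd.simulate_stillface_session("high_sr", seed=4)
        b = sd.simulate_stillface_session("high_sr", seed=4)
        np.testing.assert_array_equal(a.behavior_count, b.behavior_count)
        np.testing.assert_array_equal(a.affect, b.affect)

    def test_phase_protocol_order(self):
        rec = sd.simulate_stillface_session("low_sr", seed=1)
        labels = [p for p, _ in __import__("arousalkit.types", fromlist=["_group_runs"])._group_runs(rec.phase)]
        assert labels == ["play1", "still", "play2"]

    def test_unknown_group(self):
        with pytest.raises(ValueError):
            sd.simulate_stillface_session("mid_sr", seed=0)


class TestCohort:
    def test_cohort_csvs_schema(self, tmp_path):
        recs, sf = sd.simulate_cohort(4, seed=0, masks_config=sd.MasksConfig(duration_s=1800.0))
        paths = sd.write_cohort_csvs(recs, sf, str(tmp_path))
        import pandas as pd
        rr = pd.read_csv(paths["rr"])
        assert set(rr.columns) == {"participant_id", "beat_time_s", "rr_ms"}
        assert (rr["rr_ms"] > 0).all()
        ev = pd.read_csv(paths["vocal_events"])
        assert set(ev["speaker"]) <= {"infant", "adult"}
        import json
        truth = json.load(open(paths["ground_truth"]))
        assert set(truth) == set(recs)
        assert truth["p001"]["group"] == "low_sr"
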