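import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from arousalkit.types import ModelParams
from arousalkit import mean_reversion_model as mrm, synthetic_data as sd
from arousalkit.poincare_stability import DegenerateInputError, quantile_bin


def brute_force_complete_runs(cond, valid):
    """Loop oracle: lengths of condition runs bounded by valid non-runs."""
    lengths = []
    n = len(cond)
    i = 0
    while i < n:
        if cond[i] and valid[i]:
            j = i
            while j < n and cond[j] and valid[j]:
                j += 1
            left_ok = i > 0 and valid[i - 1] and not (cond[i - 1] and valid[i - 1])
            right_ok = j < n and valid[j]
            if left_ok and right_ok:
                lengths.append(j - i)
            i = j
        else:
            i += 1
    return lengths


class TestEpisodeDurations:
    def test_interior_runs_only(self):
        # [1,1,-1,1,1,1,-1] around 0: first hyper run touches the start
        # and is excluded; the interior run has length 3
        v = np.array([1.0, 1.0, -1.0, 1.0, 1.0, 1.0, -1.0])
        stats = mrm.episode_durations(v, mu=0.0)
        assert stats.mean_hyper_dur == 3.0
        assert stats.n_hyper == 1
        assert stats.mean_hypo_dur == 1.0  # idx 2 only; idx 6 touches the end
        assert stats.n_hypo == 1

    def test_alternating_all_length_one(self):
        v = np.tile([1.0, -1.0], 10)
        stats = mrm.episode_durations(v, mu=0.0)
        assert stats.mean_hyper_dur == 1.0
        assert stats.mean_hypo_dur == 1.0

    def test_both_classes_present_when_variance_positive(self, rng):
        v = rng.standard_normal(500)
        stats = mrm.episode_durations(v)
        assert stats.n_hyper > 0 and stats.n_hypo > 0 and stats.n_mid > 0

    def test_gap_truncated_runs_excluded(self):
        v = np.array([-1.0, 1.0, 1.0, -1.0, 1.0, -1.0])
        valid = np.array([True, True, True, False, True, True])
        stats = mrm.episode_durations(v, valid=valid, mu=0.0)
        # run at idx 1-2 is followed by an invalid epoch -> truncated
        assert np.isnan(stats.mean_hyper_dur)

    @given(
        st.lists(st.floats(-3, 3), min_size=4, max_size=50),
        st.data(),
    )
    @settings(max_examples=80)
    def test_oracle_equivalence(self, values, data):
        v = np.asarray(values)
        valid = np.asarray(
            data.draw(st.lists(st.booleans(), min_size=v.size, max_size=v.size))
        )
        if valid.sum() < 2:
            return
        mu = float(np.mean(v[valid]))
        stats = mrm.episode_durations(v, valid=valid, mu=mu)
        oracle = brute_force_complete_runs(v > mu, valid)
        if oracle:
            assert stats.mean_hyper_dur == pytest.approx(np.mean(oracle))
            assert stats.n_hyper == len(oracle)
        else:
            assert np.isnan(stats.mean_hyper_dur)

    def test_batch_matches_single(self, rng):
        batch = rng.standard_normal((20, 100))
        hyper, hypo = mrm.batch_episode_ratios(batch)
        for i in range(20):
            stats = mrm.episode_durations(batch[i])
            for mine, ref in ((hyper[i], stats.hyper_ratio), (hypo[i], stats.hypo_ratio)):
                if np.isnan(ref):
                    assert np.isnan(mine)
                else:
                    assert mine == pytest.approx(ref)


class TestGoodnessOfFit:
    def test_self_consistency_near_zero(self):
        params = ModelParams(0.5, 0.3, 0.0, 1.0)
        big = sd.simulate_arousal_batch(params, 2050, 400, rng=np.random.default_rng(1))[:, 50:]
        h, l = mrm.batch_episode_ratios(big)
        observed = mrm.EpisodeStats(
            float(np.nanmean(h)), float(np.nanmean(l)), 1.0, 1, 1, 1)
        # inject ratios directly: mean_mid_dur 1 so ratios equal the means
        hd, ld = mrm.goodness_of_fit(observed, params, n_sim=400, n_epochs=2000, seed=2)
        assert abs(hd) < 0.15 and abs(ld) < 0.15

    def test_sigma_zero_flagged(self):
        observed = mrm.EpisodeStats(2.0, 2.0, 1.0, 5, 5, 5)
        params = ModelParams(0.5, 0.5, 0.0, 0.0)
        hd, ld = mrm.goodness_of_fit(observed, params, n_sim=5, n_epochs=100, seed=0)
        assert np.isnan(hd) and np.isnan(ld)

    def test_low_beta_pos_gives_negative_hyper_discrepancy(self):
        # episodes simulated at beta_pos near 0 are longer than observed
        # at 0.5 -> observed minus simulated is negative
        truth = ModelParams(0.5, 0.5, 0.0, 1.0)
        obs_series = sd.simulate_arousal_series(truth, 3000, seed=3)
        observed = mrm.episode_durations(obs_series.values)
        slow = ModelParams(0.05, 0.5, 0.0, 1.0)
        hd, _ = mrm.goodness_of_fit(observed, slow, n_sim=100, n_epochs=3000, seed=4)
        assert hd < 0

    def test_mean_hyper_duration_monotone_in_beta_pos(self):
        rng = np.random.default_rng(9)
        means = []
        for bp in (0.1, 0.4, 0.7, 1.0):
            sims = sd.simulate_arousal_batch(
                ModelParams(bp, 0.5, 0.0, 1.0), 1550, 200, rng=rng)[:, 50:]
            mu = sims.mean(axis=1, keepdims=True)
            means.append(np.nanmean(mrm._batch_run_means(sims > mu)))
        assert all(a >= b - 0.05 for a, b in zip(means, means[1:]))

    def test_symmetric_betas_symmetric_ratios(self):
        params = ModelParams(0.4, 0.4, 0.0, 1.0)
        sims = sd.simulate_arousal_batch(params, 2050, 300, rng=np.random.default_rng(5))[:, 50:]
        h, l = mrm.batch_episode_ratios(sims)
        assert np.nanmean(h) == pytest.approx(np.nanmean(l), rel=0.05)


class TestFitSurfaceAndBestFit:
    def _surface_with_minimum(self, at=(0.5, 0.2)):
        grid = np.asarray(mrm.DEFAULT_BETA_GRID)
        hyper = np.abs(grid[:, None] - at[0]) + 0.05
        hypo = np.abs(grid[None, :] - at[1]) + 0.05
        i = int(round(at[0] * 10))
        j = int(round(at[1] * 10))
        hyper = np.broadcast_to(hyper, (11, 11)).copy()
        hypo = np.broadcast_to(hypo, (11, 11)).copy()
        hyper[i, :] = 0.0
        hypo[:, j] = 0.0
        return mrm.FitSurface(grid, hyper, hypo, n_sim=1, seed=0)

    def test_zero_discrepancy_cell_recovered(self):
        surface = self._surface_with_minimum((0.5, 0.2))
        assert mrm.best_fit(surface) == (0.5, 0.2)
        assert mrm.best_fit(surface, joint=False) == (0.5, 0.2)

    def test_tie_resolves_to_smaller_beta(self):
        grid = np.asarray(mrm.DEFAULT_BETA_GRID)
        flat = np.ones((11, 11))
        flat[3, :] = 0.1
        flat[4, :] = 0.1  # tie between 0.3 and 0.4
        surface = mrm.FitSurface(grid, flat, np.ones((11, 11)), 1, 0)
        bp, _ = mrm.best_fit(surface, joint=False)
        assert bp == 0.3

    def test_all_flagged_rejected(self):
        grid = np.asarray(mrm.DEFAULT_BETA_GRID)
        nanmat = np.full((11, 11), np.nan)
        with pytest.raises(ValueError):
            mrm.best_fit(mrm.FitSurface(grid, nanmat, nanmat, 1, 0))

    def test_surface_computable_with_n_sim_one(self):
        observed = mrm.EpisodeStats(2.0, 2.0, 1.3, 5, 5, 5)
        surface = mrm.fit_surface(observed, grid=(0.2, 0.8), n_sim=1,
                                  n_epochs=120, seed=0)
        assert surface.hyper_discrepancy.shape == (2, 2)

    def test_fit_surface_matches_goodness_of_fit_statistically(self):
        observed = mrm.EpisodeStats(3.0, 3.0, 1.3, 10, 10, 10)
        surface = mrm.fit_surface(observed, grid=(0.3,), n_sim=300,
                                  n_epochs=500, seed=1)
        params = ModelParams(0.3, 0.3, 0.0, 1.0)
        hd, ld = mrm.goodness_of_fit(observed, params, n_sim=300,
                                     n_epochs=500, seed=2)
        assert surface.hyper_discrepancy[0, 0] == pytest.approx(hd, abs=0.2)
        assert surface.hypo_discrepancy[0, 0] == pytest.approx(ld, abs=0.2)


class TestRecoverySmall:
    def test_beta_neg_recovery_short(self):
        # reduced-scale sanity check; the acceptance suite runs the
        # full-scale version
        true = ModelParams(0.5, 0.2, 0.0, 1.0)
        bns = []
        for seed in (1, 2, 3):
            series = sd.simulate_arousal_series(true, 4000, seed=seed)
            _, bf = mrm.fit_participant(series.values, n_sim=40, seed=100 + seed)
            bns.append(bf[1])
        assert np.median(bns) == pytest.approx(0.2, abs=0.1)


class TestCompareFitGroups:
    def test_identical_groups_null(self, rng):
        fits = {}
        labels = {}
        vals = rng.uniform(0, 1, 20)
        for i in range(20):
            fits[f"p{i}"] = (float(vals[i]), float(vals[i]))
            labels[f"p{i}"] = "a" if i % 2 == 0 else "b"
        # same marginal distribution by construction of alternating draws
        df = mrm.compare_fit_groups(fits, labels)
        assert set(df["parameter"]) == {"beta_pos", "beta_neg"}
        assert (df["p"] > 0.01).all()

    def test_differing_beta_neg_detected(self, rng):
        fits, labels = {}, {}
        for i in range(29):
            fits[f"a{i}"] = (0.5 + rng.normal(0, 0.1), 0.2 + rng.normal(0, 0.1))
            labels[f"a{i}"] = "low"
            fits[f"b{i}"] = (0.5 + rng.normal(0, 0.1), 0.5 + rng.normal(0, 0.1))
            labels[f"b{i}"] = "high"
        df = mrm.compare_fit_groups(fits, labels).set_index("parameter")
        assert df.loc["beta_neg", "p"] < 0.01
        assert df.loc["beta_pos", "p"] > 0.05
        assert abs(df.loc["beta_neg", "Z"]) > 2

    def test_empty_fits_rejected(self):
        with pytest.raises(ValueError):
            mrm.compare_fit_groups({}, {})
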