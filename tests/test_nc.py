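import numpy as np
import pandas as pd
import pytest

import natcont as ncp
from natcont.nc import (
    Session,
    default_target_times,
    fit_readout,
    forward_average_target,
    nc_score,
    nc_sweep,
    score_features,
    shuffle_songs,
    simulate_session,
)
from natcont.songs import Mode, SongAnnotation


def flat_session(duration=100.0, speed=5.0, rate=10.0, session_id="s"):
    t = np.arange(0.0, duration, 1.0 / rate)
    beh = pd.DataFrame({"t_s": t, "walking_speed_mm_s": np.full(t.size, speed)})
    song = SongAnnotation(session_id, ((10.0, 20.0, Mode.SINE),), duration)
    return Session(session_id=session_id, song=song, behavior=beh)


class TestSimulateSession:
    def test_quiet_session_zero_activity(self):
        s = flat_session()
        quiet = Session("q", SongAnnotation("q", (), 100.0), s.behavior)
        pop = ncp.sample_population(3, seed=0)
        rec = simulate_session(pop, quiet)
        assert np.all(rec.activity == 0)

    def test_single_neuron_matches_ma_simulate(self):
        s = flat_session()
        p = ncp.MAParams(tau_int=5.0, tau_a=0.5, x_s=1.0, x_p=0.5)
        pop = ncp.PopulationParams(neurons=(p,))
        times = np.array([15.0, 30.0, 60.0])
        rec = simulate_session(pop, s, target_times=times, dt_song=0.01)
        raster = ncp.rasterize(s.song, 0.01)
        full = ncp.ma_simulate(p, raster).r
        idx = np.searchsorted(raster.bin_ends, times + 1e-9) - 1
        np.testing.assert_allclose(rec.activity[:, 0], full[idx])

    def test_causality(self):
        """Song edits after time t leave activity at t unchanged."""
        pop = ncp.sample_population(2, seed=1)
        beh_t = np.arange(0, 100, 0.1)
        beh = pd.DataFrame({"t_s": beh_t, "walking_speed_mm_s": np.ones_like(beh_t)})
        song_a = SongAnnotation("a", ((5.0, 10.0, Mode.SINE),), 100.0)
        song_b = SongAnnotation("b", ((5.0, 10.0, Mode.SINE), (60.0, 80.0, Mode.PULSE)), 100.0)
        times = np.array([20.0, 40.0, 59.0])
        rec_a = simulate_session(pop, Session("a", song_a, beh), target_times=times)
        rec_b = simulate_session(pop, Session("b", song_b, beh), target_times=times)
        np.testing.assert_allclose(rec_a.activity, rec_b.activity)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            simulate_session(ncp.sample_population(1, seed=0), flat_session(), model="glm")


class TestForwardAverageTarget:
    def test_constant_speed(self):
        s = flat_session(speed=7.5)
        t, v = forward_average_target(s, window=1.0)
        assert np.allclose(v, 7.5)

    def test_step_change_fully_forward(self):
        T = 50.0
        bt = np.arange(0, 100, 0.1)
        beh = pd.DataFrame({"t_s": bt, "walking_speed_mm_s": (bt > T).astype(float)})
        s = Session("s", SongAnnotation("s", (), 100.0), beh)
        t, v = forward_average_target(s, window=1.0, target_times=np.array([T]))
        assert v[0] == pytest.approx(1.0)

    def test_minute_window_same_code_path(self):
        s = flat_session(duration=200.0, speed=3.0)
        t, v = forward_average_target(s, window=60.0)
        assert t.size > 0 and np.allclose(v, 3.0)
        assert t.max() <= 140.0 + 1e-9  # windows stay inside the session

    def test_window_exceeding_session_rejected(self):
        with pytest.raises(ValueError):
            forward_average_target(flat_session(duration=10.0), window=20.0)


class TestFitReadout:
    def test_large_alpha_shrinks_to_mean(self, rng):
        X = rng.normal(size=(200, 5))
        y = X @ rng.normal(size=5) + 3.0
        ro = fit_readout([X], [y], alpha=1e12)
        assert np.abs(ro.weights).max() < 1e-6
        assert np.allclose(ro.predict(X), y.mean(), atol=1e-4)

    def test_recovers_known_weights(self, rng):
        X = rng.normal(size=(500, 4))
        w = np.array([1.0, -2.0, 0.5, 3.0])
        y = X @ w + 1.0
        ro = fit_readout([X], [y], alpha=1e-8)
        # map standardized weights back to raw scale
        raw_w = ro.weights / ro.feature_sd
        np.testing.assert_allclose(raw_w, w, rtol=1e-3)

    def test_matches_normal_equations(self, rng):
        X = rng.normal(size=(100, 6))
        y = rng.normal(size=100)
        alpha = 2.5
        ro = fit_readout([X], [y], alpha=alpha)
        mu, sd = X.mean(0), X.std(0)
        Z = (X - mu) / sd
        Zc = Z - Z.mean(0)
        w = np.linalg.solve(Zc.T @ Zc + alpha * np.eye(6), Zc.T @ (y - y.mean()))
        np.testing.assert_allclose(ro.weights, w, atol=1e-8)


class TestNCScore:
    def test_exact_readout_recovered(self, small_study):
        sessions, truth = small_study
        sc = nc_score(truth["pop"], sessions, n_splits=10, seed=0)
        assert sc.mean_ve > 0.99

    def test_shuffled_target_no_signal(self, small_study, rng):
        """Permuting the target in time destroys the time-locked signal;
        only (at most) session-mean structure can survive, so the score
        collapses far below the unshuffled one and shows no net skill."""
        sessions, truth = small_study
        feats, targs, targs_orig = [], [], []
        for s in sessions:
            times, y = forward_average_target(s)
            rec = simulate_session(truth["pop"], s, target_times=times)
            feats.append(rec)
            targs_orig.append(y)
            targs.append(rng.permutation(y))
        sc_orig = score_features(feats, targs_orig, n_splits=10, seed=0)
        sc = score_features(feats, targs, n_splits=10, seed=0)
        assert sc.mean_ve < 0.2
        assert sc.mean_ve < sc_orig.mean_ve - 0.5

    def test_ve_never_exceeds_one(self, small_study):
        sessions, truth = small_study
        sc = nc_score(truth["pop"], sessions, n_splits=10, seed=3)
        assert np.all(sc.ve_per_split <= 1.0)

    def test_session_level_splits_no_leakage(self):
        """Any session's rows are wholly in train or wholly in test."""
        from natcont.nc import _session_splits

        for train, test in _session_splits(10, 50, 0.8, seed=1):
            assert set(train) | set(test) == set(range(10))
            assert not set(train) & set(test)
            assert len(train) == 8

    def test_neuron_order_invariance(self, small_study):
        sessions, truth = small_study
        perm = np.random.default_rng(0).permutation(len(truth["pop"]))
        shuffled_pop = ncp.PopulationParams(
            neurons=tuple(truth["pop"].neurons[i] for i in perm))
        a = nc_score(truth["pop"], sessions, n_splits=5, seed=2, alpha=1.0)
        b = nc_score(shuffled_pop, sessions, n_splits=5, seed=2, alpha=1.0)
        np.testing.assert_allclose(a.ve_per_split, b.ve_per_split, atol=1e-8)

    def test_noise_floor_matches_variance_ratio(self):
        """With behavior = w.activity + noise, the held-out VE drops below the
        noiseless ceiling by the noise-to-signal variance ratio (the 1-second
        forward window averages ~10 behavior samples, shrinking the effective
        noise variance accordingly)."""
        def study_ve(noise):
            cfg = ncp.SyntheticStudyConfig(n_sessions=10, session_duration=300.0,
                                           noise_sd=noise, seed=11)
            sessions, truth = ncp.make_synthetic_study(cfg)
            feats, targs = [], []
            for s in sessions:
                times, y = forward_average_target(s)
                feats.append(simulate_session(truth["pop"], s, target_times=times))
                targs.append(y)
            sc = score_features(feats, targs, alpha=1e-6, n_splits=10, seed=0)
            return sc.mean_ve, np.var(np.concatenate(targs))

        ve0, _ = study_ve(0.0)
        assert ve0 > 0.99
        n_per = 10  # behavior samples per forward window
        ves = []
        for noise in (0.2, 0.5, 1.0):
            ve, var_y = study_ve(noise)
            expected = ve0 - (noise**2 / n_per) / var_y
            assert ve == pytest.approx(expected, abs=0.06)
            ves.append(ve)
        assert ve0 > ves[0] > ves[1] > ves[2]

    def test_too_few_sessions_rejected(self, small_study):
        sessions, truth = small_study
        with pytest.raises(ValueError):
            nc_score(truth["pop"], sessions[:1], n_splits=2)


class TestShuffleSongs:
    def test_two_sessions_swap(self, small_study):
        sessions, _ = small_study
        pair = sessions[:2]
        shuffled = shuffle_songs(pair, seed=0)
        assert shuffled[0].song.intervals == pair[1].song.intervals
        assert shuffled[1].song.intervals == pair[0].song.intervals

    def test_derangement_and_reproducibility(self, small_study):
        sessions, _ = small_study
        a = shuffle_songs(sessions, seed=5)
        b = shuffle_songs(sessions, seed=5)
        for x, y, orig in zip(a, b, sessions):
            assert x.song.intervals == y.song.intervals
            assert x.song.intervals != orig.song.intervals
            assert x.behavior is orig.behavior

    def test_degrades_prediction(self, small_study):
        sessions, truth = small_study
        sc = nc_score(truth["pop"], sessions, n_splits=10, seed=1)
        sc_sh = nc_score(truth["pop"], shuffle_songs(sessions, seed=2),
                         n_splits=10, seed=1)
        assert sc_sh.mean_ve < sc.mean_ve

    def test_single_session_rejected(self, small_study):
        with pytest.raises(ValueError):
            shuffle_songs(small_study[0][:1], seed=0)


class TestBaselines:
    def test_constant_speed_timestamp_r2(self):
        # constant target has zero variance -> VE convention 0; the baseline
        # machinery must run and produce the convention value, not crash
        sessions = [flat_session(session_id=f"s{i}") for i in range(4)]
        scores = ncp.baseline_predictors(sessions, which=("timestamp",),
                                         n_splits=5, seed=0)
        assert np.allclose(scores["timestamp"].ve_per_split, 0.0)

    def test_bout_duration_baseline_captures_bout_built_behavior(self):
        """Behavior constructed from the trailing bout-duration signal is
        well predicted by the bout-duration baseline."""
        rng = np.random.default_rng(3)
        sessions = []
        for i in range(6):
            song = ncp.generate_song(ncp.SongGenParams(), 240.0, 100 + i)
            bt = np.arange(0.0, 240.0, 0.1)
            _, bd, _ = ncp.bout_stats(song, window=120.0, times=bt)
            beh = pd.DataFrame({"t_s": bt, "walking_speed_mm_s": 5.0 + bd})
            sessions.append(Session(f"s{i}", song, beh))
        scores = ncp.baseline_predictors(sessions, which=("bout_duration",),
                                         n_splits=8, seed=0)
        assert scores["bout_duration"].mean_ve > 0.9

    def test_baselines_share_split_seed(self, small_study):
        sessions, truth = small_study
        sc = nc_score(truth["pop"], sessions, n_splits=6, seed=9)
        base = ncp.baseline_predictors(sessions, which=("timestamp", "linear_filter"),
                                       n_splits=6, seed=9)
        # identical protocol: per-split VEs are paired (same split count)
        for v in base.values():
            assert v.ve_per_split.size == sc.ve_per_split.size


@pytest.fixture(scope="module")
def tiny_study():
    cfg = ncp.SyntheticStudyConfig(n_sessions=4, session_duration=60.0,
                                   n_neurons=6, noise_sd=0.2, seed=5)
    return ncp.make_synthetic_study(cfg)


class TestSweeps:
    def test_full_rank_pcs_equal_unprojected(self, tiny_study):
        sessions, truth = tiny_study
        factory = lambda n, seed: ncp.sample_population(n, seed=seed)
        tab = nc_sweep(factory, sessions, "n_pcs", base_pop=truth["pop"],
                       pcs_grid=[len(truth["pop"])], n_splits=4, seed=1, alpha=1.0)
        sc = nc_score(truth["pop"], sessions, n_splits=4, seed=1, alpha=1.0)
        assert tab["mean_ve"].iloc[0] == pytest.approx(sc.mean_ve, abs=1e-6)

    def test_regime_grid_enumeration(self, tiny_study):
        sessions, truth = tiny_study
        factory = lambda n, seed: ncp.sample_population(n, seed=seed)
        tab = nc_sweep(factory, sessions, "regime_grid", base_pop=truth["pop"],
                       n_splits=2, seed=1, alpha=1.0)
        assert len(tab) == 12  # 3 tau_int x (3 tau_a + none)
        assert set(tab["tau_a_regime"]) == {"fast", "medium", "slow", "none"}

    def test_population_size_nondecreasing_in_expectation(self, tiny_study):
        sessions, truth = tiny_study
        factory = lambda n, seed: ncp.sample_population(n, seed=seed)
        tab = nc_sweep(factory, sessions, "population_size", sizes=(1, 8),
                       n_instantiations=6, n_splits=4, seed=2, alpha=1.0)
        assert tab["mean_ve"].iloc[1] >= tab["mean_ve"].iloc[0]

    def test_heterogeneity_table_shape(self, tiny_study):
        sessions, truth = tiny_study
        factory = lambda n, seed: ncp.sample_population(n, seed=seed)
        tab = nc_sweep(factory, sessions, "heterogeneity", n_splits=2, seed=3,
                       alpha=1.0, base_pop=truth["pop"])
        assert set(tab["config"]) == {"het_tau_a_fixed_tau_int",
                                      "het_tau_int_fixed_tau_a"}

    def test_unknown_sweep_rejected(self, tiny_study):
        sessions, _ = tiny_study
        with pytest.raises(ValueError):
            nc_sweep(lambda n, s: None, sessions, "banana")


def test_manifest_roundtrip(tmp_path, small_study):
    sessions, _ = small_study
    from natcont.synthetic import write_study

    manifest = write_study(sessions[:2], tmp_path)
    back = ncp.nc.read_session_manifest(manifest)
    assert len(back) == 2
    by_id = {s.session_id: s for s in back}
    orig = sessions[0]
    got = by_id[orig.session_id]
    assert len(got.song.intervals) == len(orig.song.intervals)
    for (s1, e1, m1), (s2, e2, m2) in zip(got.song.intervals, orig.song.intervals):
        assert (s1, e1) == pytest.approx((s2, e2), abs=1e-9)
        assert m1 == m2
    np.testing.assert_allclose(got.behavior["walking_speed_mm_s"],
                               orig.behavior["walking_speed_mm_s"])
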