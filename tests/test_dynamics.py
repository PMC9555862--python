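"""NNLS decomposition, VIF, subset selection, RDM movies, start times."""

import numpy as np
import pytest

from neurorsa.dynamics import (
    MixtureCoefficients,
    bootstrap_dynamics,
    decompose_movie,
    nnls_decompose,
    rdm_movie,
    select_model_subset,
    start_time,
    start_times,
    timing_difference_test,
    vif,
)
from neurorsa.models import normalize, somatotopy_rdm
from neurorsa.rdm import crossnobis
from neurorsa.spikes import bin_firing_rates
from neurorsa.synth import Component, GroundTruthGeometry, SessionConfig, simulate_dynamics, simulate_session

from conftest import random_embeddable_rdm


def orthogonal_pair(seed=0):
    rng = np.random.default_rng(seed)
    a = rng.random(10) + 0.2
    a /= np.linalg.norm(a)
    b = rng.standard_normal(10)
    b -= (b @ a) * a
    b /= np.linalg.norm(b)
    return a, b


class TestNnlsDecompose:
    def test_recovers_planted_coefficient(self):
        a, b = orthogonal_pair()
        mix = nnls_decompose(1.7 * a, [a, b], l2_normalize=False)
        assert np.allclose(mix.coefficients, [1.7, 0.0], atol=1e-12)

    def test_zero_data_zero_coefficients(self):
        a, b = orthogonal_pair(1)
        mix = nnls_decompose(np.zeros(10), [a, b])
        assert np.allclose(mix.coefficients, 0.0)

    def test_negative_direction_clamped_at_zero(self):
        a, b = orthogonal_pair(2)
        mix = nnls_decompose(-a, [a], l2_normalize=False)
        assert mix.coefficients[0] == 0.0
        assert mix.residual_norm == pytest.approx(1.0)

    def test_empty_basis_rejected(self):
        with pytest.raises(ValueError):
            nnls_decompose(np.ones(10), [])

    @pytest.mark.parametrize("seed", range(5))
    def test_nested_basis_never_increases_residual(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(10)
        basis = [rng.random(10) for _ in range(3)]
        r2 = nnls_decompose(y, basis[:2]).residual_norm
        r3 = nnls_decompose(y, basis).residual_norm
        assert r3 <= r2 + 1e-12


class TestVif:
    def test_orthogonal_basis_unity(self):
        a, b = orthogonal_pair(3)
        rep = vif([a, b], mode="both")
        assert np.allclose(rep.vif_ols, 1.0, atol=1e-8)
        assert np.allclose(rep.vif_nnls, 1.0, atol=1e-8)

    def test_duplicate_model_infinite(self):
        a, _ = orthogonal_pair(4)
        rep = vif([a, a.copy()], mode="both")
        assert np.isinf(rep.vif_ols).all()
        assert np.isinf(rep.vif_nnls).all()

    def test_constructed_r2_gives_exact_vif(self):
        # y = x + residual with centered R² exactly 0.8
        x = np.zeros(10)
        x[0] = 1.0
        e = np.zeros(10)
        e[1] = 0.5  # var ratio: R² = 1/(1+0.25) = 0.8
        y = x + e
        rep = vif([y, x], mode="ols", l2_normalize=False)
        assert rep.vif_ols[0] == pytest.approx(5.0, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_regression_oracle(self, seed):
        import statsmodels.api as sm

        rng = np.random.default_rng(seed)
        basis = [rng.random(10) for _ in range(3)]
        rep = vif(basis, mode="ols", l2_normalize=True)
        mats = np.stack([b / np.linalg.norm(b) for b in basis], axis=1)
        for j in range(3):
            rest = np.delete(mats, j, axis=1)
            fit = sm.OLS(mats[:, j], rest).fit()  # zero-intercept, uncentered R²
            assert rep.vif_ols[j] == pytest.approx(1 / (1 - fit.rsquared), abs=1e-10)

    def test_needs_two_models(self):
        with pytest.raises(ValueError):
            vif([np.ones(10)])


class TestSubsetSelection:
    def test_recovers_generating_single_model(self, session_rdm_factory):
        a, b = orthogonal_pair(5)
        rdms = np.asarray(session_rdm_factory(2.0 * a, n_sessions=8, noise_sd=0.1, seed=0))
        res = select_model_subset(rdms, {"A": a, "B": b},
                                  [("A",), ("B",), ("A", "B")], seed=0)
        assert res["chosen"] == ("A",)

    def test_identical_fits_pick_smallest(self, session_rdm_factory):
        a, _ = orthogonal_pair(6)
        rdms = np.asarray(session_rdm_factory(a, n_sessions=6, noise_sd=0.05, seed=1))
        res = select_model_subset(rdms, {"A": a, "A2": a.copy()},
                                  [("A",), ("A", "A2")], seed=0)
        assert res["chosen"] == ("A",)

    def test_collinear_subset_flagged(self, session_rdm_factory):
        a, b = orthogonal_pair(7)
        near = a + 0.05 * b
        rdms = np.asarray(session_rdm_factory(a, n_sessions=6, noise_sd=0.1, seed=2))
        res = select_model_subset(rdms, {"A": a, "near": near},
                                  [("A",), ("A", "near")], seed=0)
        flags = {tuple(r["subset"]): r["vif_flagged"] for r in res["table"]}
        assert flags[("A", "near")]
        assert not flags[("A",)]

    def test_needs_three_sessions(self):
        with pytest.raises(ValueError):
            select_model_subset(np.ones((2, 10)), {"A": np.ones(10)}, [("A",)])


@pytest.fixture(scope="module")
def stationary_session():
    cfg = SessionConfig(n_neurons=25, runs_per_session=2, blocks_per_run=3,
                        baseline_rate=12.0, bin_width=0.02, seed=31)
    geo = GroundTruthGeometry([Component("g", random_embeddable_rdm(6, scale=3.0, seed=4),
                                         onset=-0.5, rise_time=0.0)])
    return simulate_session(cfg, geo)


class TestRdmMovie:
    def test_stationary_geometry_flat_in_time(self, stationary_session):
        s = stationary_session
        cfg = s.config
        times, movie = rdm_movie(s.spike_counts, s.labels, cfg.bin_width, cfg.cue_time,
                                 window=0.4, step=0.25, n_folds=3, seed=0,
                                 time_range=(0.3, 2.2))
        mean_dist = np.array([m.distances.mean() for m in movie])
        slope = np.polyfit(times, mean_dist, 1)[0]
        assert abs(slope) < 0.2 * (abs(mean_dist.mean()) + 1e-9) / (times[-1] - times[0])

    def test_pre_cue_distances_near_zero(self):
        cfg = SessionConfig(n_neurons=20, runs_per_session=2, blocks_per_run=2,
                            baseline_rate=10.0, bin_width=0.02, cue_time=1.0, seed=32)
        geo = GroundTruthGeometry([Component("g", random_embeddable_rdm(6, scale=3.0, seed=1),
                                             onset=0.1, rise_time=0.1)])
        s = simulate_session(cfg, geo)
        times, movie = rdm_movie(s.spike_counts, s.labels, cfg.bin_width, cfg.cue_time,
                                 window=0.4, step=0.5, n_folds=3, seed=0,
                                 time_range=(-0.8, 1.6))
        pre = np.concatenate([m.distances for t, m in zip(times, movie) if t < -0.2])
        post = np.concatenate([m.distances for t, m in zip(times, movie) if t > 0.8])
        assert abs(pre.mean()) < 0.1 * post.mean()

    def test_full_trial_window_matches_static_rdm(self, stationary_session):
        s = stationary_session
        cfg = s.config
        duration = cfg.n_bins * cfg.bin_width
        times, movie = rdm_movie(s.spike_counts, s.labels, cfg.bin_width, cfg.cue_time,
                                 window=duration, step=10.0, n_folds=3, seed=5,
                                 time_range=(duration / 2 - cfg.cue_time,
                                             duration / 2 - cfg.cue_time))
        rates = s.spike_counts.sum(axis=2) / duration
        static = crossnobis(rates, s.labels, n_folds=3, seed=5)
        assert len(movie) == 1
        assert np.allclose(movie[0].distances, static.distances, atol=1e-10)

    def test_window_longer_than_trial_rejected(self, stationary_session):
        s = stationary_session
        with pytest.raises(ValueError):
            rdm_movie(s.spike_counts, s.labels, s.config.bin_width, window=10.0)


class TestStartTime:
    def test_never_exceeding_is_nan(self):
        t = np.arange(10) * 0.1
        assert np.isnan(start_time(t, np.full(10, 0.1)))

    def test_step_series_onset(self):
        t = np.arange(20) * 0.05
        c = np.r_[np.zeros(12), np.ones(8)]
        assert start_time(t, c) == pytest.approx(t[12])

    def test_zero_threshold_first_bin(self):
        t = np.arange(5) * 0.1
        assert start_time(t, np.ones(5), threshold=0.0) == pytest.approx(0.0)

    def test_strictly_greater_than(self):
        t = np.arange(3) * 0.1
        c = np.array([0.2, 0.2, 0.3])  # equality does not trigger
        assert start_time(t, c, threshold=0.2) == pytest.approx(t[2])


class TestTimingDifference:
    def test_identical_onsets_p_one(self):
        a = np.linspace(0.1, 0.4, 6)
        med, p = timing_difference_test(a, a.copy())
        assert med == 0.0 and p == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0.1, 0.3, 8)
        b = a + rng.uniform(0.1, 0.2, 8)
        m1, _ = timing_difference_test(a, b)
        m2, _ = timing_difference_test(b, a)
        assert m1 == pytest.approx(-m2)

    def test_planted_lag_detected(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0.1, 0.2, 10)
        b = a + 0.3 + rng.normal(0, 0.01, 10)
        med, p = timing_difference_test(a, b)
        assert med == pytest.approx(0.3, abs=0.02)
        assert p < 0.01

    def test_nan_pairs_dropped(self):
        a = np.r_[np.linspace(0.1, 0.2, 6), np.nan]
        b = a + 0.1
        med, p = timing_difference_test(a, b)
        assert med == pytest.approx(0.1)

    def test_too_few_defined_pairs(self):
        with pytest.raises(ValueError):
            timing_difference_test(np.array([0.1, np.nan, 0.2]), np.array([0.2, 0.3, np.nan]))


class TestBootstrapDynamics:
    @staticmethod
    def toy_movies(n_sessions, seed=0):
        from neurorsa.rdm import RDM, FINGERS

        rng = np.random.default_rng(seed)
        a, b = orthogonal_pair(9)
        times = np.arange(0, 1.0, 0.1)
        movies = []
        for _ in range(n_sessions):
            movie = []
            for t in times:
                vec = (t > 0.2) * a * 2 + (t > 0.5) * b * 1.5 + rng.normal(0, 0.05, 10)
                movie.append(RDM(FINGERS, vec, timepoint=float(t)))
            movies.append(movie)
        return movies, a, b

    def test_single_draw_equals_point_estimate(self):
        movies, a, b = self.toy_movies(3)
        res = bootstrap_dynamics(movies, [a, b], n_boot=1, seed=0)
        point = decompose_movie([type(r)(r.conditions,
                                         np.mean([m[i].distances for m in movies], axis=0),
                                         timepoint=r.timepoint)
                                 for i, r in enumerate(movies[0])], [a, b])
        assert np.allclose(res.coefficients, point.coefficients)
        assert np.allclose(res.bootstrap_bands, 0.0)

    def test_seed_determinism(self):
        movies, a, b = self.toy_movies(4)
        r1 = bootstrap_dynamics(movies, [a, b], n_boot=50, seed=3)
        r2 = bootstrap_dynamics(movies, [a, b], n_boot=50, seed=3)
        assert np.allclose(r1.bootstrap_bands, r2.bootstrap_bands)

    def test_bands_shrink_with_more_sessions(self):
        small, a, b = self.toy_movies(3, seed=1)
        large, _, _ = self.toy_movies(12, seed=1)
        r_small = bootstrap_dynamics(small, [a, b], n_boot=100, seed=0)
        r_large = bootstrap_dynamics(large, [a, b], n_boot=100, seed=0)
        assert r_large.bootstrap_bands.mean() < r_small.bootstrap_bands.mean()


@pytest.mark.parametrize("lag", [0.0, 0.3])
def test_end_to_end_lag_recovery(lag):
    """The dynamics pipeline recovers a planted component lag to within one
    sliding-window step across sessions."""
    step = 0.1
    a = random_embeddable_rdm(6, scale=4.0, seed=10)
    b = random_embeddable_rdm(6, scale=4.0, seed=20)
    a5 = a[:5, :5][np.triu_indices(5, 1)]
    b5 = b[:5, :5][np.triu_indices(5, 1)]
    onsets_a, onsets_b = [], []
    for sess in range(6):
        cfg = SessionConfig(n_neurons=30, runs_per_session=2, blocks_per_run=3,
                            baseline_rate=15.0, bin_width=0.02, seed=100 + sess)
        s = simulate_dynamics(cfg, a, b, lag=lag, onset_a=0.2, rise_time=0.1,
                              session_index=sess)
        times, movie = rdm_movie(s.spike_counts, s.labels, cfg.bin_width, cfg.cue_time,
                                 window=0.2, step=step, n_folds=3, seed=0,
                                 time_range=(-0.3, 2.0))
        mix = decompose_movie(movie, [a5, b5])
        st = start_times(mix, threshold=0.2 * np.max(mix.coefficients))
        onsets_a.append(st.onsets[0])
        onsets_b.append(st.onsets[1])
    med = np.median(np.asarray(onsets_b) - np.asarray(onsets_a))
    assert abs(med - lag) <= step + 1e-9
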