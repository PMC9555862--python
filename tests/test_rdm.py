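"""Crossnobis / Poisson-KL estimators: oracles, unbiasedness, invariances."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from neurorsa.rdm import (
    RDM,
    crossnobis,
    matrix_to_rdm,
    n_pairs,
    pair_labels,
    poisson_skl,
    rdm_to_matrix,
    shrinkage_cov,
    stratified_folds,
)

from conftest import random_embeddable_rdm


def brute_force_crossnobis(rates, labels, fold, conditions, covs):
    """Literal transcription of the estimator: for each unordered fold pair
    (A, B), d² = (b̄j−b̄k)_A [(Σ_A+Σ_B)/2]⁻¹ (b̄j−b̄k)_Bᵀ / N, averaged."""
    n_units = rates.shape[1]
    n_folds = len(covs)
    means = []
    for f in range(n_folds):
        means.append({c: rates[(fold == f) & (labels == c)].mean(axis=0) for c in conditions})
    out = []
    for j, k in combinations(conditions, 2):
        vals = []
        for a, b in combinations(range(n_folds), 2):
            sig = np.linalg.inv((covs[a] + covs[b]) / 2)
            d = (means[a][j] - means[a][k]) @ sig @ (means[b][j] - means[b][k]) / n_units
            vals.append(d)
        out.append(np.mean(vals))
    return np.array(out)


class TestVectorization:
    def test_pair_count_and_labels(self):
        assert n_pairs(5) == 10
        labs = pair_labels(("T", "I", "M", "R", "P"))
        assert labs[0] == "T-I" and labs[-1] == "R-P" and len(labs) == 10

    def test_matrix_round_trip(self):
        v = np.arange(10, dtype=float) - 3  # negatives allowed
        assert np.allclose(matrix_to_rdm(rdm_to_matrix(v)), v)

    def test_matrix_validation(self):
        with pytest.raises(ValueError, match="symmetric"):
            matrix_to_rdm(np.array([[0, 1], [2, 0.0]]))
        with pytest.raises(ValueError, match="diagonal"):
            matrix_to_rdm(np.array([[1.0, 1], [1, 0]]))

    def test_rdm_length_check(self):
        with pytest.raises(ValueError):
            RDM(("a", "b", "c"), np.zeros(5))


class TestStratifiedFolds:
    def test_per_condition_balance(self):
        labels = np.repeat(list("TIMRPX"), 10)
        fold = stratified_folds(labels, 5, np.random.default_rng(0))
        for c in "TIMRPX":
            counts = np.bincount(fold[labels == c], minlength=5)
            assert np.all(counts == 2)

    def test_too_few_trials_raises(self):
        with pytest.raises(ValueError, match="T"):
            stratified_folds(np.array(["T"] * 3 + ["I"] * 9), 5, np.random.default_rng(0))


class TestCrossnobis:
    def test_matches_brute_force_transcription(self):
        rng = np.random.default_rng(0)
        labels = np.repeat(list("ab"), 6)
        rates = rng.normal(5.0, 1.0, size=(12, 4))
        est = crossnobis(rates, labels, n_folds=2, seed=1, drop=(), conditions=("a", "b"))
        fold = stratified_folds(labels, 2, np.random.default_rng(1))
        covs = []
        for f in range(2):
            sel = fold == f
            m = {c: rates[sel & (labels == c)].mean(axis=0) for c in "ab"}
            resid = rates[sel] - np.stack([m[c] for c in labels[sel]])
            covs.append(shrinkage_cov(resid).matrix)
        oracle = brute_force_crossnobis(rates, labels, fold, ("a", "b"), covs)
        assert np.allclose(est.distances, oracle, atol=1e-12)

    def test_planted_difference_closed_form(self):
        # Gaussian noise, identity whitening: E[d²] = ||δ||² / N
        rng = np.random.default_rng(2)
        n_units, n_trials = 30, 400
        delta = np.zeros(n_units)
        delta[:10] = 1.0
        est = []
        for _ in range(5):
            a = rng.standard_normal((n_trials, n_units))
            b = rng.standard_normal((n_trials, n_units)) + delta
            rates = np.vstack([a, b])
            labels = np.array(["a"] * n_trials + ["b"] * n_trials)
            r = crossnobis(rates, labels, n_folds=5, seed=0, drop=(), noise="identity")
            est.append(r.distances[0])
        expected = delta @ delta / n_units
        assert np.mean(est) == pytest.approx(expected, rel=0.1)

    def test_null_mean_near_zero(self):
        rng = np.random.default_rng(3)
        vals = []
        for i in range(200):
            rates = rng.poisson(5.0, size=(40, 20)).astype(float)
            labels = np.array(["a", "b"] * 20)
            vals.append(crossnobis(rates, labels, n_folds=5, seed=i, drop=()).distances[0])
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean()) < 3 * se

    def test_scaling_quadratic_under_identity_whitening(self):
        rng = np.random.default_rng(4)
        rates = rng.normal(10, 2, size=(30, 8))
        labels = np.array(["a", "b", "c"] * 10)
        base = crossnobis(rates, labels, n_folds=3, seed=0, drop=(), noise="identity")
        scaled = crossnobis(3 * rates, labels, n_folds=3, seed=0, drop=(), noise="identity")
        assert np.allclose(scaled.distances, 9 * base.distances, rtol=1e-10)

    def test_fold_count_invariance_in_expectation(self):
        rng = np.random.default_rng(5)
        delta = np.r_[np.ones(5), np.zeros(15)]
        est = {2: [], 5: []}
        for i in range(40):
            a = rng.standard_normal((50, 20))
            b = rng.standard_normal((50, 20)) + delta
            rates, labels = np.vstack([a, b]), np.array(["a"] * 50 + ["b"] * 50)
            for k in (2, 5):
                est[k].append(
                    crossnobis(rates, labels, n_folds=k, seed=i, drop=(), noise="identity").distances[0]
                )
        se = np.std(np.array(est[2]) - np.array(est[5])) / np.sqrt(40)
        assert abs(np.mean(est[2]) - np.mean(est[5])) < 4 * se + 0.02

    def test_no_go_dropped_by_default(self, small_session):
        from neurorsa.spikes import bin_firing_rates

        cfg = small_session.config
        fr = bin_firing_rates(small_session.spike_counts, (0.5, 1.5), cfg.bin_width,
                              cfg.cue_time, labels=small_session.labels)
        r = crossnobis(fr.rates, fr.labels, n_folds=4, seed=0)
        assert r.conditions == ("T", "I", "M", "R", "P")
        assert len(r.distances) == 10

    def test_missing_condition_trials_error(self):
        rates = np.random.default_rng(0).normal(size=(8, 3))
        labels = np.array(["a"] * 6 + ["b"] * 2)
        with pytest.raises(ValueError, match="b"):
            crossnobis(rates, labels, n_folds=5, drop=())


class TestShrinkageCov:
    def test_large_n_approaches_sample_cov(self):
        # genuinely correlated truth: the optimal diagonal-target weight -> 0
        rng = np.random.default_rng(0)
        truth = np.array([[2.0, 0.8, 0.3], [0.8, 1.5, 0.6], [0.3, 0.6, 1.0]])
        x = rng.multivariate_normal(np.zeros(3), truth, size=5000)
        nc = shrinkage_cov(x)
        assert nc.shrinkage_weight < 0.05
        assert np.allclose(nc.matrix, np.cov(x.T), atol=0.05)

    def test_positive_definite_when_wide(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((5, 40))  # features > trials
        nc = shrinkage_cov(x)
        assert np.linalg.eigvalsh(nc.matrix).min() > 0

    def test_beats_sample_cov_for_diagonal_truth(self):
        rng = np.random.default_rng(2)
        truth = np.diag(np.linspace(1, 3, 12))
        x = rng.multivariate_normal(np.zeros(12), truth, size=15)
        nc = shrinkage_cov(x)
        err_shrunk = np.linalg.norm(nc.matrix - truth)
        err_sample = np.linalg.norm(np.cov(x.T) - truth)
        assert err_shrunk < err_sample
        # off-diagonals pulled toward zero
        off = ~np.eye(12, dtype=bool)
        assert np.abs(nc.matrix[off]).sum() < np.abs(np.cov(x.T)[off]).sum()

    def test_matches_sklearn_in_well_conditioned_limit(self):
        # different shrinkage targets, but both must converge on the truth
        from sklearn.covariance import LedoitWolf

        rng = np.random.default_rng(3)
        truth = np.array([[2.0, 0.8, 0.3], [0.8, 1.5, 0.6], [0.3, 0.6, 1.0]])
        x = rng.multivariate_normal(np.zeros(3), truth, size=4000)
        ours = shrinkage_cov(x).matrix
        theirs = LedoitWolf().fit(x).covariance_
        assert np.allclose(ours, theirs, atol=0.08)


class TestPoissonSKL:
    def test_noiseless_two_rate_closed_form(self):
        # one unit, rates 2 vs 8 in every trial: (λ1−λ2)(lnλ1−lnλ2) = 6 ln 4
        rates = np.array([[2.0]] * 10 + [[8.0]] * 10)
        labels = np.array(["a"] * 10 + ["b"] * 10)
        r = poisson_skl(rates, labels, n_folds=5, drop=())
        assert r.distances[0] == pytest.approx(6 * np.log(4), abs=1e-12)

    def test_null_expectation_zero(self):
        rng = np.random.default_rng(0)
        vals = []
        for i in range(150):
            rates = rng.poisson(6.0, size=(40, 10)).astype(float)
            labels = np.array(["a", "b"] * 20)
            vals.append(poisson_skl(rates, labels, n_folds=5, seed=i, drop=()).distances[0])
        vals = np.asarray(vals)
        assert abs(np.mean(vals)) < 4 * vals.std(ddof=1) / np.sqrt(len(vals))

    def test_rank_agreement_with_crossnobis(self):
        from neurorsa.spikes import bin_firing_rates
        from neurorsa.synth import Component, GroundTruthGeometry, SessionConfig, simulate_session

        cfg = SessionConfig(n_neurons=40, runs_per_session=3, blocks_per_run=2,
                            baseline_rate=12.0, seed=21)
        geo = GroundTruthGeometry([Component("g", random_embeddable_rdm(6, scale=3.0, seed=8),
                                             onset=0.0, rise_time=0.1)])
        s = simulate_session(cfg, geo)
        fr = bin_firing_rates(s.spike_counts, (0.5, 1.5), cfg.bin_width, cfg.cue_time,
                              labels=s.labels)
        a = crossnobis(fr.rates, fr.labels, n_folds=5, seed=0)
        b = poisson_skl(fr.rates, fr.labels, n_folds=5, seed=0)
        rho = stats.spearmanr(a.distances, b.distances).statistic
        assert rho > 0.9

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            poisson_skl(np.array([[-1.0], [1.0]]), np.array(["a", "b"]), n_folds=1, drop=())
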