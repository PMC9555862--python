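import numpy as np
import pytest

from neurorsa.rdm import matrix_to_rdm
from neurorsa.synth import Component, GroundTruthGeometry, SessionConfig, simulate_session


def random_embeddable_rdm(n_cond=5, dim=4, scale=1.0, seed=0):
    """Squared-distance matrix of random Gaussian patterns (always embeddable)."""
    rng = np.random.default_rng(seed)
    p = rng.standard_normal((n_cond, dim)) * scale
    d = ((p[:, None, :] - p[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d, 0.0)
    return d


def random_spd(n, seed=0, cond=10.0):
    rng = np.random.default_rng(seed)
    q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    eig = np.linspace(1.0, cond, n)
    return (q * eig) @ q.T


@pytest.fixture
def equilateral_rdm6():
    """6-condition RDM where every pair is 2 units² apart (embeddable)."""
    m = np.full((6, 6), 2.0)
    np.fill_diagonal(m, 0.0)
    return m


@pytest.fixture
def small_session():
    """Small tuned Poisson session: 20 units, 2 runs × 2 blocks (48 trials)."""
    cfg = SessionConfig(n_neurons=20, runs_per_session=2, blocks_per_run=2,
                        baseline_rate=8.0, seed=11)
    geo = GroundTruthGeometry([Component("geom", random_embeddable_rdm(6, scale=2.0, seed=5),
                                         onset=0.0, rise_time=0.1)])
    return simulate_session(cfg, geo)


@pytest.fixture
def session_rdm_factory():
    """Noisy session-level RDM vectors drawn around a target vector."""

    def make(target_vec, n_sessions, noise_sd, seed=0):
        rng = np.random.default_rng(seed)
        return [np.asarray(target_vec) + rng.standard_normal(len(target_vec)) * noise_sd
                for _ in range(n_sessions)]

    return make
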