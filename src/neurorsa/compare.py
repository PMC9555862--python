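"""Comparing measured RDMs with model RDMs.

Model fit is quantified with the whitened unbiased cosine similarity
(WUC): a cosine similarity under an inner product whitened by the
covariance V of the RDM entries,

    WUC(r, m) = (r V⁻¹ mᵀ) / sqrt((r V⁻¹ rᵀ)(m V⁻¹ mᵀ)).

Cosine (rather than correlation) similarity exploits the informative zero
point of the unbiased crossnobis estimator — d² = 0 means the two
conditions are identically distributed — while the whitening accounts for
the fact that distances sharing a condition covary because they share
data. Whitened Pearson correlation (WUC on mean-centered vectors) is the
conventional alternative. The noise ceiling Ĉ is the leave-one-session-out
average similarity of each session's RDM to the mean of the others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .rdm import RDM, n_pairs, shrinkage_cov

log = logging.getLogger(__name__)


@dataclass
class SimilarityResult:
    metric: str
    value: float
    model_name: str | None = None
    session_index: int | None = None
    bootstrap_distribution: np.ndarray | None = None


@dataclass
class NoiseCeiling:
    lower: float
    per_session_terms: np.ndarray


def _as_vector(r) -> np.ndarray:
    if isinstance(r, RDM):
        return r.distances
    if hasattr(r, "distances"):
        return np.asarray(r.distances, dtype=float)
    return np.asarray(r, dtype=float)


def _whitened_inner(a: np.ndarray, b: np.ndarray, v: np.ndarray) -> float:
    return float(a @ np.linalg.solve(v, b))


def wuc(data_rdm, model_rdm, whitening: np.ndarray | None = None, **meta) -> SimilarityResult:
    """Whitened unbiased cosine similarity between two RDM vectors.

    ``whitening`` is the (symmetric positive-definite) covariance of the
    RDM entries; identity reduces WUC to the plain cosine similarity.
    """
    r, m = _as_vector(data_rdm), _as_vector(model_rdm)
    if r.shape != m.shape:
        raise ValueError(f"RDM lengths differ: {r.shape} vs {m.shape}")
    v = np.eye(len(r)) if whitening is None else np.asarray(whitening, dtype=float)
    rr, mm = _whitened_inner(r, r, v), _whitened_inner(m, m, v)
    if rr <= 0 or mm <= 0:
        raise ValueError("zero-norm RDM under the whitened inner product")
    value = _whitened_inner(r, m, v) / np.sqrt(rr * mm)
    name = getattr(model_rdm, "name", None)
    return SimilarityResult(metric="wuc", value=float(value), model_name=name, **meta)


def whitened_pearson(data_rdm, model_rdm, whitening: np.ndarray | None = None, **meta) -> SimilarityResult:
    """WUC applied to mean-centered vectors (whitened Pearson correlation)."""
    r, m = _as_vector(data_rdm), _as_vector(model_rdm)
    res = wuc(r - r.mean(), m - m.mean(), whitening)
    return SimilarityResult(metric="whitened_pearson", value=res.value,
                            model_name=getattr(model_rdm, "name", None), **meta)


def shared_condition_whitening(n_conditions: int = 5) -> np.ndarray:
    """Structured fallback covariance for the RDM entries.

    V = 0.5·I + 0.25·A·Aᵀ, with A the pair×condition incidence matrix:
    unit diagonal, 0.25 between pairs sharing a condition, 0 otherwise.
    A heuristic encoding of shared-data covariance, positive definite by
    construction; used only when a single RDM estimate is available.
    """
    pairs = list(combinations(range(n_conditions), 2))
    a = np.zeros((len(pairs), n_conditions))
    for i, (j, k) in enumerate(pairs):
        a[i, [j, k]] = 1.0
    return 0.5 * np.eye(len(pairs)) + 0.25 * a @ a.T


def pair_covariance(rdms) -> np.ndarray:
    """Covariance of the RDM entries across independent estimates
    (sessions or folds), shrinkage-regularized to be invertible.

    With a single RDM the structured shared-condition approximation is
    returned instead (with a logged notice).
    """
    x = np.stack([_as_vector(r) for r in rdms])
    if x.shape[0] < 2:
        log.info("pair_covariance: single RDM, falling back to the structured approximation")
        n_cond = int((1 + np.sqrt(1 + 8 * x.shape[1])) / 2)
        return shared_condition_whitening(n_cond)
    return shrinkage_cov(x, ridge=1e-6).matrix


def noise_ceiling(rdms, metric=wuc, whitening: np.ndarray | None = None) -> NoiseCeiling:
    """Lower noise ceiling: Ĉ = (1/D) Σ_d similarity(r_d, mean of others)."""
    x = np.stack([_as_vector(r) for r in rdms])
    d = x.shape[0]
    if d < 2:
        raise ValueError("need at least 2 session RDMs")
    if whitening is None:
        whitening = pair_covariance(x)
    terms = np.empty(d)
    for i in range(d):
        others = x[np.arange(d) != i].mean(axis=0)
        terms[i] = metric(x[i], others, whitening).value
    return NoiseCeiling(lower=float(terms.mean()), per_session_terms=terms)


def bootstrap_model_contrast(
    rdms,
    model_a,
    model_b,
    n_boot: int = 1000,
    seed: int = 0,
    metric=wuc,
    whitening: np.ndarray | None = None,
) -> tuple[float, float, np.ndarray]:
    """Bootstrap (over sessions) contrast between two models' fits.

    Sessions are resampled with replacement; each bootstrap sample's mean
    RDM is compared with both models and the fit difference recorded. A
    two-tailed one-sample t-test is applied to the bootstrap distribution
    of differences. Returns (mean difference, p, bootstrap differences).
    """
    x = np.stack([_as_vector(r) for r in rdms])
    if x.shape[0] < 2:
        raise ValueError("need at least 2 session RDMs")
    if whitening is None:
        whitening = pair_covariance(x)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        sample = x[rng.integers(0, x.shape[0], x.shape[0])].mean(axis=0)
        diffs[b] = metric(sample, model_a, whitening).value - metric(sample, model_b, whitening).value
    t, p = stats.ttest_1samp(diffs, 0.0)
    return float(diffs.mean()), float(p), diffs


def typicality_permutation(
    target_rdm,
    population_rdms,
    n_perm: int = 1000,
    seed: int = 0,
    metric=wuc,
    whitening: np.ndarray | None = None,
) -> tuple[float, float]:
    """Permutation shuffle test of whether a target RDM is typical of a
    population of RDMs.

    Statistic: similarity of the target to the population mean. Null:
    exchange the target with a randomly chosen population member and
    recompute. p = fraction of permuted statistics ≤ the observed one
    (small p → the target fits the population worse than its members do),
    with the +1 correction so p ≥ 1/(n_perm+1).
    """
    pop = np.stack([_as_vector(r) for r in population_rdms])
    if pop.shape[0] < 5:
        raise ValueError("need a population of at least 5 RDMs")
    t = _as_vector(target_rdm)
    if whitening is None:
        whitening = pair_covariance(np.vstack([pop, t[None]]))
    observed = metric(t, pop.mean(axis=0), whitening).value
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        i = rng.integers(0, pop.shape[0])
        swapped = pop.copy()
        new_target, swapped[i] = pop[i].copy(), t
        stat = metric(new_target, swapped.mean(axis=0), whitening).value
        count += stat <= observed
    return observed, float((count + 1) / (n_perm + 1))


# ---------------------------------------------------------------------------
# low-dimensional geometry: classical MDS + Generalized Procrustes (no scaling)


def classical_mds(rdm, n_dims: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of an RDM to ``n_dims`` dimensions.

    Negative distance estimates are floored at 0 for the embedding only.
    """
    from .rdm import rdm_to_matrix

    d = _as_vector(rdm)
    mat = rdm_to_matrix(np.maximum(d, 0.0))
    n = mat.shape[0]
    c = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * c @ mat @ c
    eigval, eigvec = np.linalg.eigh(gram)
    order = np.argsort(eigval)[::-1][:n_dims]
    comp = eigvec[:, order] * np.sqrt(np.clip(eigval[order], 0.0, None))
    return comp


def generalized_procrustes(
    configs: list[np.ndarray],
    max_iter: int = 100,
    tol: float = 1e-12,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Generalized Procrustes alignment with rotation/reflection and
    translation but NO scaling, so inter-point distances are preserved.

    Returns (aligned configurations, consensus mean configuration).
    """
    from scipy.linalg import orthogonal_procrustes

    aligned = [np.asarray(c, dtype=float) - np.asarray(c, dtype=float).mean(axis=0) for c in configs]
    mean = aligned[0].copy()
    prev = np.inf
    for _ in range(max_iter):
        for i, c in enumerate(aligned):
            rot, _ = orthogonal_procrustes(c, mean)
            aligned[i] = c @ rot
        mean = np.mean(aligned, axis=0)
        resid = sum(((c - mean) ** 2).sum() for c in aligned)
        if prev - resid < tol * (1 + resid):
            break
        prev = resid
    return aligned, mean


def mds_and_procrustes(rdms, n_dims: int = 2) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-session classical MDS followed by Generalized Procrustes
    alignment (no scaling). Returns aligned 2-D configurations and their
    consensus."""
    configs = [classical_mds(r, n_dims=n_dims) for r in rdms]
    return generalized_procrustes(configs)
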