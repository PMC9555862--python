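"""Cross-validated representational dissimilarity estimation.

The central quantity is the crossnobis (cross-validated squared Mahalanobis)
distance between condition-evoked firing-rate patterns,

    d²_jk = (b̄_j − b̄_k)_A · [(Σ_A + Σ_B)/2]⁻¹ · (b̄_j − b̄_k)_Bᵀ / N ,

averaged over all unordered pairs of independent trial partitions (A, B).
Because the two difference vectors come from independent data, the estimator
is unbiased: its expectation is 0 when the two conditions' firing-rate
distributions are identical, and estimates may legitimately be negative.
Distances are reported in unitless²/neuron (the 1/N puts populations of
different size on a common scale).

A Poisson symmetrized-KL alternative is provided as a robustness check; it
shares the fold scheme and vectorization conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform

FINGERS = ("T", "I", "M", "R", "P")
CONDITIONS = FINGERS + ("X",)  # X = No-Go
NO_GO = "X"


def n_pairs(n_conditions: int) -> int:
    """Number of unique unordered condition pairs (RDM vector length)."""
    return n_conditions * (n_conditions - 1) // 2


def pair_labels(conditions: Sequence[str]) -> list[str]:
    """Condition-pair names in the fixed vectorization order.

    The order is the row-major upper triangle of the RDM matrix, i.e.
    (0,1), (0,2), ..., (0,n-1), (1,2), ... — identical to the convention
    used by :func:`scipy.spatial.distance.squareform`.
    """
    return [f"{a}-{b}" for a, b in combinations(conditions, 2)]


def rdm_to_matrix(distances: np.ndarray) -> np.ndarray:
    """Unique-pair vector -> symmetric zero-diagonal matrix."""
    return squareform(np.asarray(distances, dtype=float), checks=False)


def matrix_to_rdm(matrix: np.ndarray, atol: float = 1e-10) -> np.ndarray:
    """Symmetric zero-diagonal matrix -> unique-pair vector (row-major upper triangle)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {matrix.shape}")
    if not np.allclose(matrix, matrix.T, atol=atol):
        raise ValueError("matrix is not symmetric")
    if not np.allclose(np.diag(matrix), 0.0, atol=atol):
        raise ValueError("matrix diagonal is not zero")
    return squareform(0.5 * (matrix + matrix.T), checks=False)


@dataclass
class RDM:
    """Vector of unique cross-validated squared pairwise distances.

    Entries may be negative (the estimator is unbiased, not a metric);
    they are never clipped here.
    """

    conditions: tuple[str, ...]
    distances: np.ndarray
    session_index: int | None = None
    timepoint: float | None = None

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        self.distances = np.asarray(self.distances, dtype=float)
        expected = n_pairs(len(self.conditions))
        if self.distances.shape != (expected,):
            raise ValueError(
                f"{len(self.conditions)} conditions require {expected} distances, "
                f"got shape {self.distances.shape}"
            )

    @property
    def matrix(self) -> np.ndarray:
        return rdm_to_matrix(self.distances)

    @property
    def pair_labels(self) -> list[str]:
        return pair_labels(self.conditions)


@dataclass
class NoiseCovariance:
    """Shrinkage-regularized noise covariance (features × features)."""

    matrix: np.ndarray
    shrinkage_weight: float


def shrinkage_cov(residuals: np.ndarray, ridge: float = 1e-10) -> NoiseCovariance:
    """Shrink the sample covariance of residuals toward its diagonal.

    Uses the analytic Schäfer–Strimmer weight for the diagonal target:
    the off-diagonal entries of the sample covariance are scaled by
    (1 − λ*) with λ* = Σ Var̂(s_ij) / Σ s_ij² over i ≠ j. A tiny ridge
    keeps the result positive definite even for zero-variance features.

    Parameters
    ----------
    residuals : (n_trials, n_features) array
        Rows are mean-centered observations (centering is re-applied here).
    """
    x = np.asarray(residuals, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 residual rows")
    n, p = x.shape
    x = x - x.mean(axis=0, keepdims=True)
    s = x.T @ x / (n - 1)

    # variance of each covariance entry (Schäfer & Strimmer 2005, target D)
    w = x[:, :, None] * x[:, None, :]          # n × p × p products
    var_s = n / (n - 1) ** 3 * ((w - w.mean(axis=0)) ** 2).sum(axis=0)
    off = ~np.eye(p, dtype=bool)
    denom = float((s[off] ** 2).sum())
    lam = 1.0 if denom == 0.0 else float(np.clip(var_s[off].sum() / denom, 0.0, 1.0))

    shrunk = (1.0 - lam) * s
    np.fill_diagonal(shrunk, np.diag(s))
    eps = ridge * (np.trace(shrunk) / p + 1.0)
    shrunk = shrunk + eps * np.eye(p)
    return NoiseCovariance(matrix=shrunk, shrinkage_weight=lam)


def stratified_folds(
    labels: np.ndarray, n_folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Assign each trial to one of `n_folds` folds, stratified by condition.

    Per condition, trials are shuffled and dealt round-robin so fold sizes
    per condition differ by at most one. Deterministic given the generator
    state. Raises if any condition has fewer trials than folds.
    """
    labels = np.asarray(labels)
    fold = np.empty(len(labels), dtype=int)
    for cond in np.unique(labels):
        idx = np.flatnonzero(labels == cond)
        if len(idx) < n_folds:
            raise ValueError(
                f"condition {cond!r} has {len(idx)} trials, fewer than {n_folds} folds"
            )
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    return fold


def _fold_stats(rates, labels, fold, conditions, n_folds):
    """Per fold: condition-mean patterns and within-condition residuals."""
    means, resids = [], []
    for f in range(n_folds):
        sel = fold == f
        r, l = rates[sel], labels[sel]
        m = np.stack([r[l == c].mean(axis=0) for c in conditions])
        lookup = {c: i for i, c in enumerate(conditions)}
        res = r - m[[lookup[c] for c in l]]
        means.append(m)
        resids.append(res)
    return means, resids


def _resolve_conditions(labels, conditions, drop):
    labels = np.asarray(labels)
    if conditions is None:
        present = [c for c in CONDITIONS if c in labels]
        extras = sorted(set(labels) - set(CONDITIONS))
        conditions = tuple(present) + tuple(extras)
    conditions = tuple(c for c in conditions if c not in set(drop))
    keep = np.isin(labels, conditions)
    return labels, conditions, keep


def crossnobis(
    rates: np.ndarray,
    labels: Sequence,
    n_folds: int = 5,
    seed: int = 0,
    conditions: Sequence[str] | None = None,
    drop: Sequence[str] = (NO_GO,),
    noise: str | np.ndarray = "shrinkage",
    session_index: int | None = None,
    timepoint: float | None = None,
) -> RDM:
    """Cross-validated squared Mahalanobis RDM from trial firing rates.

    Trials are stratified-split into ``n_folds`` non-overlapping subsets;
    the crossnobis distance is computed for every unordered pair of folds
    and averaged. The noise covariance is estimated per fold from residuals
    around that fold's condition means and shrinkage-regularized, or can be
    supplied (``noise="identity"`` or an explicit matrix) for oracle tests.

    The No-Go condition is dropped by default, leaving the 10 unique
    inter-finger distances.
    """
    rates = np.asarray(rates, dtype=float)
    labels, conditions, keep = _resolve_conditions(labels, conditions, drop)
    rates, labels = rates[keep], labels[keep]
    n_units = rates.shape[1]
    rng = np.random.default_rng(seed)
    fold = stratified_folds(labels, n_folds, rng)
    means, resids = _fold_stats(rates, labels, fold, conditions, n_folds)

    if isinstance(noise, str) and noise == "shrinkage":
        covs = [shrinkage_cov(r).matrix for r in resids]
    elif isinstance(noise, str) and noise == "identity":
        covs = [np.eye(n_units)] * n_folds
    else:
        covs = [np.asarray(noise, dtype=float)] * n_folds

    pairs = list(combinations(range(len(conditions)), 2))
    acc = np.zeros(len(pairs))
    fold_pairs = list(combinations(range(n_folds), 2))
    for a, b in fold_pairs:
        sigma = 0.5 * (covs[a] + covs[b])
        delta_a = np.stack([means[a][j] - means[a][k] for j, k in pairs])
        delta_b = np.stack([means[b][j] - means[b][k] for j, k in pairs])
        acc += np.einsum("pi,pi->p", delta_a, np.linalg.solve(sigma, delta_b.T).T)
    distances = acc / (len(fold_pairs) * n_units)
    return RDM(conditions, distances, session_index=session_index, timepoint=timepoint)


def poisson_skl(
    rates: np.ndarray,
    labels: Sequence,
    n_folds: int = 5,
    seed: int = 0,
    conditions: Sequence[str] | None = None,
    drop: Sequence[str] = (NO_GO,),
    rate_floor: float = 0.01,
    session_index: int | None = None,
    timepoint: float | None = None,
) -> RDM:
    """Cross-validated symmetrized Poisson KL-divergence RDM.

    For independent Poisson units with rates λ, the symmetrized KL between
    conditions j and k is Σ_units (λ_j − λ_k)(ln λ_j − ln λ_k). The
    cross-validated version takes the rate differences from one fold and
    the log-rate differences from another, symmetrized over the fold pair,
    normalized by the number of units. Rates are floored before the log.
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    labels, conditions, keep = _resolve_conditions(labels, conditions, drop)
    rates, labels = rates[keep], labels[keep]
    n_units = rates.shape[1]
    rng = np.random.default_rng(seed)
    fold = stratified_folds(labels, n_folds, rng)
    means, _ = _fold_stats(rates, labels, fold, conditions, n_folds)
    logs = [np.log(np.maximum(m, rate_floor)) for m in means]

    pairs = list(combinations(range(len(conditions)), 2))
    acc = np.zeros(len(pairs))
    fold_pairs = list(combinations(range(n_folds), 2))
    for a, b in fold_pairs:
        for p, (j, k) in enumerate(pairs):
            term_ab = (means[a][j] - means[a][k]) @ (logs[b][j] - logs[b][k])
            term_ba = (means[b][j] - means[b][k]) @ (logs[a][j] - logs[a][k])
            acc[p] += 0.5 * (term_ab + term_ba)
    distances = acc / (len(fold_pairs) * n_units)
    return RDM(conditions, distances, session_index=session_index, timepoint=timepoint)
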