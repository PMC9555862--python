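"""Spike-level preprocessing: threshold crossings, PCA feature selection,
k-medoids sorting with the gap criterion, L-ratio unit quality, firing-rate
windowing, and single-unit tuning statistics.

The chain mirrors standard intracortical practice: events are detected at
−3.5× the RMS of the voltage trace, waveform snippets are reduced to the
first n ∈ {2,3,4} principal components (smallest n explaining ≥95% of
variance), clustered with k-medoids where the number of clusters is chosen
by the gap statistic, and cluster isolation is quantified by the L-ratio
with a threshold of 10^−1.1 separating well-isolated single units from
potential multiunits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from statsmodels.stats.multitest import multipletests

from .synth import WaveformSet

log = logging.getLogger(__name__)

L_RATIO_THRESHOLD = 10 ** -1.1


@dataclass
class UnitQuality:
    l_ratio: float
    well_isolated: bool


@dataclass
class FiringRateMatrix:
    rates: np.ndarray  # trials × units, spikes/s
    window: tuple[float, float]  # s relative to cue
    labels: np.ndarray
    run_index: np.ndarray | None = None
    session_index: int | None = None


def detect_threshold_crossings(
    voltage: np.ndarray,
    fs: float,
    multiplier: float = -3.5,
    lockout: float = 0.001,
) -> np.ndarray:
    """Event times (s) where the trace crosses multiplier × RMS downward.

    A refractory lockout (default 1 ms) suppresses re-triggering on the
    same waveform. An all-zero trace has RMS 0 and yields no events.
    """
    if multiplier >= 0:
        raise ValueError("multiplier must be negative (downward crossings)")
    v = np.asarray(voltage, dtype=float)
    rms = float(np.sqrt(np.mean(v**2)))
    if rms == 0.0:
        return np.array([])
    thr = multiplier * rms
    below = v < thr
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if v[0] < thr:
        crossings = np.concatenate([[0], crossings])
    lock = max(1, int(round(lockout * fs)))
    kept, last = [], -lock - 1
    for i in crossings:
        if i - last > lock:
            kept.append(i)
            last = i
    return np.asarray(kept) / fs


def choose_n_pcs(snippets: WaveformSet | np.ndarray, variance_target: float = 0.95) -> int:
    """Smallest n ∈ {2,3,4} of principal components reaching the variance
    target (95%); capped at 4 if none does."""
    x = snippets.snippets if isinstance(snippets, WaveformSet) else np.asarray(snippets, float)
    if x.shape[0] < 5:
        raise ValueError("need at least 5 snippets")
    x = x - x.mean(axis=0)
    s = np.linalg.svd(x, compute_uv=False)
    var = s**2
    frac = np.cumsum(var) / var.sum()
    frac = np.pad(frac, (0, max(0, 4 - len(frac))), constant_values=1.0)
    for n in (2, 3, 4):
        if frac[n - 1] >= variance_target:
            return n
    return 4


def pca_features(snippets: WaveformSet | np.ndarray, n_pcs: int | None = None) -> np.ndarray:
    """Project snippets onto their first principal components."""
    x = snippets.snippets if isinstance(snippets, WaveformSet) else np.asarray(snippets, float)
    if n_pcs is None:
        n_pcs = choose_n_pcs(x)
    xc = x - x.mean(axis=0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    return xc @ vt[:n_pcs].T


def _kmedoids_once(dist: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 100):
    """Voronoi-iteration k-medoids (PAM-lite) on a precomputed distance matrix."""
    n = dist.shape[0]
    # k-medoids++ seeding
    medoids = [int(rng.integers(n))]
    for _ in range(k - 1):
        d2 = dist[:, medoids].min(axis=1) ** 2
        total = d2.sum()
        if total == 0:
            medoids.append(int(rng.integers(n)))
        else:
            medoids.append(int(rng.choice(n, p=d2 / total)))
    medoids = np.asarray(medoids)
    for _ in range(max_iter):
        labels = np.argmin(dist[:, medoids], axis=1)
        new = medoids.copy()
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members) == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            new[c] = members[np.argmin(within)]
        if np.array_equal(np.sort(new), np.sort(medoids)):
            break
        medoids = new
    labels = np.argmin(dist[:, medoids], axis=1)
    cost = float(dist[np.arange(n), medoids[labels]].sum())
    return labels, cost


def kmedoids(features: np.ndarray, k: int, seed: int = 0, n_restarts: int = 3) -> np.ndarray:
    """Cluster feature vectors into k groups; best of several seeded restarts."""
    x = np.asarray(features, dtype=float)
    if k > x.shape[0]:
        raise ValueError(f"k={k} exceeds {x.shape[0]} events")
    dist = cdist(x, x)
    best_labels, best_cost = None, np.inf
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        labels, cost = _kmedoids_once(dist, k, rng)
        if cost < best_cost:
            best_labels, best_cost = labels, cost
    return best_labels


def _within_dispersion(features: np.ndarray, labels: np.ndarray) -> float:
    """Tibshirani's W_k = Σ_r D_r / (2 n_r) with squared Euclidean distances."""
    w = 0.0
    for c in np.unique(labels):
        m = features[labels == c]
        centroid = m.mean(axis=0)
        w += ((m - centroid) ** 2).sum()  # equals Σ d²_{ii'} / (2 n_r)
    return w


def sort_kmedoids_gap(
    features: np.ndarray,
    k_max: int = 5,
    seed: int = 0,
    n_ref: int = 20,
    n_restarts: int = 3,
) -> tuple[np.ndarray, int]:
    """Choose the number of waveform clusters by the gap statistic and
    return k-medoids labels at that k.

    Gap(k) = E*[log W_k] − log W_k against ``n_ref`` uniform reference
    draws over the feature bounding box; the chosen k is the smallest with
    Gap(k) ≥ Gap(k+1) − s_{k+1} (one-standard-error criterion).
    """
    x = np.asarray(features, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > x.shape[0]:
        raise ValueError(f"k_max={k_max} exceeds {x.shape[0]} events")
    rng = np.random.default_rng(seed)
    lo, hi = x.min(axis=0), x.max(axis=0)

    labels_k, log_w = {}, np.empty(k_max)
    ref_log_w = np.empty((n_ref, k_max))
    refs = [rng.uniform(lo, hi, size=x.shape) for _ in range(n_ref)]
    for k in range(1, k_max + 1):
        labels_k[k] = kmedoids(x, k, seed=seed + k, n_restarts=n_restarts)
        log_w[k - 1] = np.log(max(_within_dispersion(x, labels_k[k]), 1e-300))
        for b, ref in enumerate(refs):
            rl = kmedoids(ref, k, seed=seed + 1000 + b * k_max + k, n_restarts=1)
            ref_log_w[b, k - 1] = np.log(max(_within_dispersion(ref, rl), 1e-300))

    gap = ref_log_w.mean(axis=0) - log_w
    s = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1 + 1 / n_ref)
    chosen = k_max
    for k in range(1, k_max):
        if gap[k - 1] >= gap[k] - s[k]:
            chosen = k
            break
    return labels_k[chosen], chosen


def l_ratio(
    cluster_features: np.ndarray,
    noise_features: np.ndarray,
    threshold: float = L_RATIO_THRESHOLD,
) -> UnitQuality:
    """Cluster-isolation L-ratio.

    L = Σ over non-cluster events of P(χ²_df > D²) where D² is the event's
    squared Mahalanobis distance to the cluster (df = feature dimension);
    L-ratio = L / n_cluster. ``well_isolated`` iff L-ratio < 10^−1.1.
    A singular cluster covariance is shrunk toward its diagonal with a
    logged ridge.
    """
    xc = np.atleast_2d(np.asarray(cluster_features, dtype=float))
    xn = np.atleast_2d(np.asarray(noise_features, dtype=float))
    n, p = xc.shape
    if n <= p:
        raise ValueError(f"cluster needs more events ({n}) than feature dims ({p})")
    mean = xc.mean(axis=0)
    cov = np.cov(xc.T, ddof=1).reshape(p, p)
    ridge, tries = 0.0, 0
    while True:
        try:
            chol = np.linalg.cholesky(cov + ridge * np.eye(p))
            break
        except np.linalg.LinAlgError:
            tries += 1
            ridge = max(ridge * 10, 1e-8 * (np.trace(cov) / p + 1.0))
            if tries > 12:
                raise
    if ridge:
        log.warning("l_ratio: singular cluster covariance, ridge=%.3e applied", ridge)
    z = np.linalg.solve(chol, (xn - mean).T)
    d2 = (z**2).sum(axis=0)
    l = float(stats.chi2.sf(d2, df=p).sum())
    ratio = l / n
    return UnitQuality(l_ratio=ratio, well_isolated=ratio < threshold)


def bin_firing_rates(
    spike_counts: np.ndarray,
    window: tuple[float, float],
    bin_width: float,
    cue_time: float = 0.0,
    labels: np.ndarray | None = None,
    run_index: np.ndarray | None = None,
    session_index: int | None = None,
) -> FiringRateMatrix:
    """Firing rates (spikes/s) per trial × unit in a window relative to cue.

    ``spike_counts`` is trials × units × time bins covering the trial from
    t=0 in steps of ``bin_width``. The rate is the count in the window
    divided by the window length actually covered by whole bins.
    """
    counts = np.asarray(spike_counts)
    start, end = window
    if end <= start:
        raise ValueError("window end must exceed start")
    lo = int(np.ceil((cue_time + start) / bin_width - 1e-9))
    hi = int(np.floor((cue_time + end) / bin_width + 1e-9))
    lo, hi = max(lo, 0), min(hi, counts.shape[2])
    if hi <= lo:
        raise ValueError(f"window {window} covers no whole bins within the trial")
    duration = (hi - lo) * bin_width
    rates = counts[:, :, lo:hi].sum(axis=2) / duration
    return FiringRateMatrix(
        rates=rates.astype(float),
        window=(start, end),
        labels=np.asarray(labels) if labels is not None else None,
        run_index=np.asarray(run_index) if run_index is not None else None,
        session_index=session_index,
    )


def tuning_tests(
    fr: FiringRateMatrix,
    no_go: str = "X",
    alpha: float = 0.05,
    min_rate: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-unit, per-finger tuning vs the No-Go condition.

    Two-tailed t-test of each movement's firing rate against No-Go, with
    Benjamini–Hochberg FDR across the whole unit × finger family.
    d′ = mean rate difference / RMS of the two SDs. Units with mean rate
    below ``min_rate`` (0.1 Hz) are excluded. A unit's ``best_finger`` is
    its significant finger with the largest absolute mean rate change.

    Returns (per unit×finger table, per-unit summary).
    """
    labels = np.asarray(fr.labels)
    if no_go not in labels:
        raise ValueError(f"No-Go condition {no_go!r} missing")
    fingers = [c for c in pd.unique(labels) if c != no_go]
    baseline = fr.rates[labels == no_go]
    mean_rate = fr.rates.mean(axis=0)
    included = mean_rate >= min_rate

    rows = []
    for u in np.flatnonzero(included):
        b = baseline[:, u]
        for f in fingers:
            x = fr.rates[labels == f, u]
            sd_pool = np.sqrt((x.std(ddof=1) ** 2 + b.std(ddof=1) ** 2) / 2)
            if sd_pool == 0:
                t, p, dprime = np.nan, 1.0, np.nan
            else:
                t, p = stats.ttest_ind(x, b)
                dprime = (x.mean() - b.mean()) / sd_pool
            rows.append(
                dict(unit=u, finger=f, t_stat=t, p_value=p,
                     mean_change=x.mean() - b.mean(), d_prime=dprime)
            )
    tests = pd.DataFrame(rows)
    if len(tests):
        tests["significant"] = multipletests(tests["p_value"], alpha=alpha, method="fdr_bh")[0]
    else:
        tests["significant"] = pd.Series(dtype=bool)

    summaries = []
    for u in range(fr.rates.shape[1]):
        row = dict(unit=u, mean_rate=mean_rate[u], included=bool(included[u]),
                   best_finger=None, n_significant=0)
        if included[u]:
            sub = tests[(tests.unit == u) & tests.significant]
            row["n_significant"] = len(sub)
            if len(sub):
                row["best_finger"] = sub.loc[sub.mean_change.abs().idxmax(), "finger"]
        summaries.append(row)
    units = pd.DataFrame(summaries)
    return tests[tests.unit.isin(np.flatnonzero(included))].reset_index(drop=True), units
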