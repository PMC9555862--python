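"""Representational dynamics: NNLS decomposition of RDMs into model
components, multicollinearity diagnostics, cross-validated model-subset
selection, sliding-window RDM movies, start-time estimation, and timing
inference.

The measured RDM (in vector form) is modeled as a zero-intercept,
non-negative linear combination of candidate model RDMs, each ℓ2-normalized
so coefficient magnitudes are comparable. Applied in a 200-ms sliding
window this yields per-timepoint mixture coefficients; a model's start
time is the first timepoint at which its coefficient exceeds 0.2, and lags
between model onsets are tested across sessions with a two-sided Wilcoxon
signed-rank test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from scipy.optimize import nnls as _nnls

from .rdm import RDM, crossnobis
from .models import ModelRDM, normalize

log = logging.getLogger(__name__)

START_THRESHOLD = 0.2
VIF_INF_TOL = 1e-10


@dataclass
class MixtureCoefficients:
    model_names: tuple[str, ...]
    coefficients: np.ndarray  # (n_models,) or (n_timepoints, n_models)
    timepoints: np.ndarray | None = None
    residual_norm: float | np.ndarray | None = None
    bootstrap_bands: np.ndarray | None = None  # ± SEM, same shape as coefficients


@dataclass
class StartTimes:
    model_names: tuple[str, ...]
    onsets: np.ndarray  # seconds; NaN where the threshold is never exceeded
    threshold: float = START_THRESHOLD


@dataclass
class VifReport:
    model_names: tuple[str, ...]
    vif_ols: np.ndarray
    vif_nnls: np.ndarray


def _basis_matrix(basis, l2_normalize: bool) -> tuple[np.ndarray, tuple[str, ...]]:
    if len(basis) == 0:
        raise ValueError("empty model basis")
    cols, names = [], []
    for i, m in enumerate(basis):
        if isinstance(m, ModelRDM):
            mm = normalize(m, "l2") if l2_normalize else m
            cols.append(mm.distances)
            names.append(m.name)
        else:
            v = np.asarray(m, dtype=float)
            if l2_normalize:
                nrm = np.linalg.norm(v)
                if nrm == 0:
                    raise ValueError("cannot l2-normalize a zero model vector")
                v = v / nrm
            cols.append(v)
            names.append(f"model_{i}")
    return np.stack(cols, axis=1), tuple(names)


def nnls_decompose(data_rdm, basis, l2_normalize: bool = True) -> MixtureCoefficients:
    """Non-negative least-squares weights of the model basis for one RDM."""
    y = data_rdm.distances if isinstance(data_rdm, RDM) else np.asarray(data_rdm, float)
    x, names = _basis_matrix(basis, l2_normalize)
    coef, resid = _nnls(x, y)
    return MixtureCoefficients(model_names=names, coefficients=coef, residual_norm=float(resid))


def _r2_ols(y: np.ndarray, x: np.ndarray) -> float:
    """Uncentered R² of a zero-intercept OLS regression (matches the
    zero-intercept decomposition the VIF diagnoses)."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    ss_res = float(((y - x @ beta) ** 2).sum())
    ss_tot = float((y**2).sum())
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def _r2_nnls(y: np.ndarray, x: np.ndarray) -> float:
    """Uncentered R² of a zero-intercept NNLS regression (∈ [0, 1])."""
    coef, resid = _nnls(x, y)
    ss_tot = float((y**2).sum())
    return 1.0 - resid**2 / ss_tot if ss_tot > 0 else 1.0


def vif(basis, mode: str = "ols", l2_normalize: bool = True) -> VifReport:
    """Variance inflation factors of each model given the others.

    VIF_j = 1 / (1 − R²) where R² comes from regressing model j on the
    remaining models — unconstrained OLS or non-negative least squares,
    both zero-intercept with uncentered R² to match the zero-intercept
    decomposition they diagnose. R² within
    ``VIF_INF_TOL`` of 1 yields the +inf sentinel. ``mode='both'`` fills
    both columns; otherwise the unused column is NaN.
    """
    x, names = _basis_matrix(basis, l2_normalize)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 models")
    out_ols = np.full(x.shape[1], np.nan)
    out_nnls = np.full(x.shape[1], np.nan)
    for j in range(x.shape[1]):
        y = x[:, j]
        rest = np.delete(x, j, axis=1)
        if mode in ("ols", "both"):
            r2 = _r2_ols(y, rest)
            out_ols[j] = np.inf if r2 >= 1 - VIF_INF_TOL else 1.0 / (1.0 - r2)
        if mode in ("nnls", "both"):
            r2 = _r2_nnls(y, rest)
            out_nnls[j] = np.inf if r2 >= 1 - VIF_INF_TOL else 1.0 / (1.0 - r2)
    return VifReport(model_names=names, vif_ols=out_ols, vif_nnls=out_nnls)


def select_model_subset(
    session_rdms,
    basis: dict[str, np.ndarray | ModelRDM],
    candidate_subsets: list[tuple[str, ...]],
    seed: int = 0,
    n_boot: int = 500,
    metric=None,
    vif_threshold: float = 5.0,
) -> dict:
    """Choose the best parsimonious model subset by leave-one-session-out
    NNLS cross-validation and the one-standard-error rule.

    For each candidate subset and each held-out session, the subset is fit
    (NNLS, ℓ2-normalized models) to the mean RDM of the training sessions
    and the reconstruction is scored against the held-out RDM (whitened
    cosine similarity by default). The SE of the best subset's mean fit is
    bootstrapped by resampling sessions; the chosen subset is the smallest
    within one SE of the best, ties broken by size then lexicographically.
    Subsets whose members have VIF > ``vif_threshold`` are flagged.
    """
    from .compare import pair_covariance, wuc

    x = np.stack([r.distances if isinstance(r, RDM) else np.asarray(r, float) for r in session_rdms])
    n_sessions = x.shape[0]
    if n_sessions < 3:
        raise ValueError("need at least 3 sessions")
    if metric is None:
        v = pair_covariance(x)
        metric = lambda a, b: wuc(a, b, v).value

    table = []
    fits = {}
    for subset in candidate_subsets:
        cols = [basis[name] for name in subset]
        mat, _ = _basis_matrix(cols, l2_normalize=True)
        per_session = np.empty(n_sessions)
        for s in range(n_sessions):
            train = x[np.arange(n_sessions) != s].mean(axis=0)
            coef, _ = _nnls(mat, train)
            pred = mat @ coef
            if not pred.any():
                per_session[s] = 0.0
            else:
                per_session[s] = metric(x[s], pred)
        flagged = False
        if len(subset) >= 2:
            rep = vif(cols, mode="both")
            flagged = bool(np.any(rep.vif_ols > vif_threshold) or np.any(rep.vif_nnls > vif_threshold))
        fits[subset] = per_session
        table.append(dict(subset=subset, mean_fit=float(per_session.mean()),
                          n_models=len(subset), vif_flagged=flagged))

    rng = np.random.default_rng(seed)
    best = max(table, key=lambda r: r["mean_fit"])
    boots = np.empty(n_boot)
    bf = fits[best["subset"]]
    for b in range(n_boot):
        boots[b] = bf[rng.integers(0, n_sessions, n_sessions)].mean()
    se = float(boots.std(ddof=1))
    threshold = best["mean_fit"] - se
    eligible = [r for r in table if r["mean_fit"] >= threshold]
    chosen = sorted(eligible, key=lambda r: (r["n_models"], tuple(r["subset"])))[0]
    for r in table:
        r["se_best"] = se
        r["chosen"] = r["subset"] == chosen["subset"]
    return dict(chosen=chosen["subset"], se=se, table=table, per_session_fits=fits)


def rdm_movie(
    spike_counts: np.ndarray,
    labels,
    bin_width: float,
    cue_time: float = 0.0,
    window: float = 0.200,
    step: float = 0.010,
    n_folds: int = 5,
    seed: int = 0,
    time_range: tuple[float, float] | None = None,
    session_index: int | None = None,
    estimator=crossnobis,
) -> tuple[np.ndarray, list[RDM]]:
    """Time-resolved RDMs from a sliding window centered at each timepoint.

    At each peri-cue timepoint t the spikes in a ``window``-long bin
    centered at t are converted to rates and passed to the crossnobis
    estimator. Windows extending past the trial edges are truncated and
    rates renormalized by the actual covered length. Returns (peri-cue
    timepoints, list of per-timepoint RDMs).
    """
    counts = np.asarray(spike_counts)
    n_bins = counts.shape[2]
    duration = n_bins * bin_width
    if window > duration:
        raise ValueError("window exceeds the trial duration")
    if time_range is None:
        time_range = (-cue_time, duration - cue_time)
    times = np.arange(time_range[0], time_range[1] + 1e-9, step)
    half = window / 2
    rdms = []
    kept_times = []
    for t in times:
        lo = int(np.floor((cue_time + t - half) / bin_width + 1e-9))
        hi = int(np.ceil((cue_time + t + half) / bin_width - 1e-9))
        lo, hi = max(lo, 0), min(hi, n_bins)
        if hi <= lo:
            continue
        rates = counts[:, :, lo:hi].sum(axis=2) / ((hi - lo) * bin_width)
        rdms.append(
            estimator(rates, labels, n_folds=n_folds, seed=seed,
                      session_index=session_index, timepoint=float(t))
        )
        kept_times.append(t)
    return np.asarray(kept_times), rdms


def decompose_movie(movie: list[RDM], basis, l2_normalize: bool = True) -> MixtureCoefficients:
    """NNLS decomposition at every timepoint of an RDM movie."""
    x, names = _basis_matrix(basis, l2_normalize)
    coefs = np.empty((len(movie), x.shape[1]))
    resid = np.empty(len(movie))
    for i, r in enumerate(movie):
        coefs[i], resid[i] = _nnls(x, r.distances)
    times = np.asarray([r.timepoint for r in movie], dtype=float)
    return MixtureCoefficients(model_names=names, coefficients=coefs,
                               timepoints=times, residual_norm=resid)


def start_time(
    timepoints: np.ndarray,
    coeff_series: np.ndarray,
    threshold: float = START_THRESHOLD,
) -> float:
    """First timepoint at which the coefficient strictly exceeds the
    threshold; NaN if it never does."""
    timepoints = np.asarray(timepoints, dtype=float)
    coeff_series = np.asarray(coeff_series, dtype=float)
    above = np.flatnonzero(coeff_series > threshold)
    return float(timepoints[above[0]]) if len(above) else float("nan")


def start_times(mix: MixtureCoefficients, threshold: float = START_THRESHOLD) -> StartTimes:
    """Per-model start times from a per-timepoint coefficient matrix."""
    if mix.timepoints is None or mix.coefficients.ndim != 2:
        raise ValueError("needs time-resolved mixture coefficients")
    onsets = np.array([
        start_time(mix.timepoints, mix.coefficients[:, j], threshold)
        for j in range(mix.coefficients.shape[1])
    ])
    return StartTimes(model_names=mix.model_names, onsets=onsets, threshold=threshold)


def timing_difference_test(
    start_times_a: np.ndarray,
    start_times_b: np.ndarray,
) -> tuple[float, float]:
    """Paired onset-lag test across sessions.

    Returns (median of onset_b − onset_a, two-sided Wilcoxon signed-rank
    p). Pairs where either onset is undefined (NaN) are dropped with a
    logged count; identical paired onsets give the maximum attainable p.
    """
    a = np.asarray(start_times_a, dtype=float)
    b = np.asarray(start_times_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    dropped = int((~ok).sum())
    if dropped:
        log.warning("timing_difference_test: dropped %d pairs with undefined onsets", dropped)
    if ok.sum() < 5:
        raise ValueError("need paired, defined onsets for at least 5 sessions")
    diff = b[ok] - a[ok]
    if np.allclose(diff, 0.0):
        return 0.0, 1.0
    res = stats.wilcoxon(diff, alternative="two-sided")
    return float(np.median(diff)), float(res.pvalue)


def bootstrap_dynamics(
    movies: list[list[RDM]],
    basis,
    n_boot: int = 500,
    seed: int = 0,
    l2_normalize: bool = True,
) -> MixtureCoefficients:
    """Bootstrap (over sessions) the per-timepoint NNLS coefficients.

    Each draw resamples sessions with replacement, averages their RDM
    movies, and decomposes the bootstrap-mean movie; the point estimate is
    the decomposition of the plain across-session mean, with bands = the
    bootstrap SEM (SD of the bootstrap coefficient distribution).
    """
    if len(movies) < 2:
        raise ValueError("need movies from at least 2 sessions")
    times = np.asarray([r.timepoint for r in movies[0]], dtype=float)
    stack = np.stack([[r.distances for r in m] for m in movies])  # S × T × 10
    x, names = _basis_matrix(basis, l2_normalize)

    def decompose(mean_movie: np.ndarray) -> np.ndarray:
        out = np.empty((mean_movie.shape[0], x.shape[1]))
        for t in range(mean_movie.shape[0]):
            out[t], _ = _nnls(x, mean_movie[t])
        return out

    point = decompose(stack.mean(axis=0))
    rng = np.random.default_rng(seed)
    if n_boot == 1:
        bands = np.zeros_like(point)
    else:
        boots = np.empty((n_boot,) + point.shape)
        for b in range(n_boot):
            sel = rng.integers(0, stack.shape[0], stack.shape[0])
            boots[b] = decompose(stack[sel].mean(axis=0))
        bands = boots.std(axis=0, ddof=1)
    return MixtureCoefficients(model_names=names, coefficients=point,
                               timepoints=times, bootstrap_bands=bands)
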