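"""Experience-dependence of the representational structure.

Inter-finger squared distances from per-(session, run) RDMs are modeled
with ordinary least squares,

    d²_jk(s, r) = β0 + β_jk + β_session·s + β_run·r ,

i.e. a finger-pair effect plus linear trends over the session index and
the run index within sessions. t-tests on the trend coefficients use a
conservative df equal to the number of RDMs entering the fit (the 10
entries of one RDM covary, so they are not counted as independent
observations). Effect sizes are Cohen's f² against the finger-pair-only
baseline. For non-significant trends, Jeffreys–Zellner–Siow Bayes factors
quantify support for the null; one-sided BFs are obtained by sampling the
posterior of the two-sided test and dividing the directional posterior
mass by the prior odds (1/2 for a symmetric prior).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import quad

from .rdm import RDM

JZS_DEFAULT_SCALE = float(np.sqrt(2) / 2)  # "medium" Cauchy prior scale


@dataclass
class TrendFit:
    beta0: float
    beta_pair: dict[str, float]
    beta_session: float
    beta_run: float
    df: int
    t_session: float
    t_run: float
    p_session: float
    p_run: float
    f2_session: float
    f2_run: float
    n_rdms: int
    residual_ss: float = float("nan")
    alternative: str = "two-sided"


@dataclass
class BayesFactorResult:
    bf10: float
    direction: str
    posterior_samples_used: int
    two_sided_bf10: float


def rdm_table(rdms: list[RDM], run_index: list[int] | None = None) -> pd.DataFrame:
    """Tidy long table (pair, session, run, distance) from per-run RDMs.

    ``run_index`` defaults to each RDM's ``timepoint`` slot being unused;
    callers normally pass explicit run indices alongside session_index
    stored on each RDM.
    """
    rows = []
    for i, r in enumerate(rdms):
        run = run_index[i] if run_index is not None else 0
        for lab, d in zip(r.pair_labels, r.distances):
            rows.append(dict(pair=lab, session=r.session_index, run=run, distance=d))
    return pd.DataFrame(rows)


def _ols(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float]:
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return beta, float((resid**2).sum())


def fit_distance_trend(
    table: pd.DataFrame,
    pairs: list[str] | None = None,
    alternative: str = "two-sided",
) -> TrendFit:
    """OLS fit of inter-finger distances on finger pair + session + run.

    ``table`` must have columns pair, session, run, distance (one row per
    RDM entry; build it with :func:`rdm_table`). Pair effects are coded
    sum-to-zero so β0 is the grand-mean distance. ``pairs`` restricts the
    fit to a subset of finger pairs (e.g. the high-error middle-ring and
    ring-pinky pairs). ``alternative`` ∈ {two-sided, greater, less}
    controls the reported trend p-values; df = number of RDMs.
    """
    df_t = table if pairs is None else table[table["pair"].isin(pairs)]
    if pairs is not None and set(pairs) - set(table["pair"].unique()):
        raise ValueError(f"unknown pair labels: {set(pairs) - set(table['pair'].unique())}")
    df_t = df_t.reset_index(drop=True)
    if df_t["session"].nunique() < 2:
        raise ValueError("need at least 2 sessions for a session trend")

    pair_names = sorted(df_t["pair"].unique())
    n = len(df_t)
    y = df_t["distance"].to_numpy(dtype=float)
    s = df_t["session"].to_numpy(dtype=float)
    r = df_t["run"].to_numpy(dtype=float)
    s_c, r_c = s - s.mean(), r - r.mean()

    # one-hot pairs (no global intercept): column means give beta0
    p_idx = pd.Categorical(df_t["pair"], categories=pair_names).codes
    onehot = np.zeros((n, len(pair_names)))
    onehot[np.arange(n), p_idx] = 1.0
    x_full = np.column_stack([onehot, s_c, r_c])
    beta, ss_res = _ols(y, x_full)
    pair_means = beta[: len(pair_names)]
    beta0 = float(pair_means.mean())
    beta_session, beta_run = float(beta[-2]), float(beta[-1])

    n_rdms = len(df_t[["session", "run"]].drop_duplicates())
    dof = n_rdms
    sigma2 = ss_res / max(n - x_full.shape[1], 1)
    xtx_inv = np.linalg.pinv(x_full.T @ x_full)
    se_session = float(np.sqrt(sigma2 * xtx_inv[-2, -2]))
    se_run = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_session = beta_session / se_session if se_session > 0 else np.nan
        t_run = beta_run / se_run if se_run > 0 else np.nan

    def pval(t):
        if not np.isfinite(t):
            return np.nan
        if alternative == "two-sided":
            return 2 * stats.t.sf(abs(t), dof)
        if alternative == "greater":
            return stats.t.sf(t, dof)
        if alternative == "less":
            return stats.t.cdf(t, dof)
        raise ValueError(f"unknown alternative {alternative!r}")

    # Cohen's f² against the finger-pair-only baseline
    _, ss_base = _ols(y, onehot)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2_full = 1 - ss_res / ss_tot if ss_tot > 0 else 0.0
    _, ss_sess = _ols(y, np.column_stack([onehot, s_c]))
    _, ss_runo = _ols(y, np.column_stack([onehot, r_c]))
    r2_sess = 1 - ss_sess / ss_tot if ss_tot > 0 else 0.0
    r2_runo = 1 - ss_runo / ss_tot if ss_tot > 0 else 0.0
    r2_base = 1 - ss_base / ss_tot if ss_tot > 0 else 0.0
    f2 = lambda r2: (r2 - r2_base) / (1 - r2) if r2 < 1 else np.inf

    return TrendFit(
        beta0=beta0,
        beta_pair={p: float(m - beta0) for p, m in zip(pair_names, pair_means)},
        beta_session=beta_session,
        beta_run=beta_run,
        df=dof,
        t_session=float(t_session),
        t_run=float(t_run),
        p_session=float(pval(t_session)),
        p_run=float(pval(t_run)),
        f2_session=float(f2(r2_sess)),
        f2_run=float(f2(r2_runo)),
        n_rdms=n_rdms,
        residual_ss=ss_res,
        alternative=alternative,
    )


def subset_trend(table: pd.DataFrame, pairs: list[str], alternative: str = "greater") -> TrendFit:
    """Trend fit restricted to listed finger pairs, one-tailed for an
    increase by default (the learning-direction hypothesis)."""
    return fit_distance_trend(table, pairs=pairs, alternative=alternative)


# ---------------------------------------------------------------------------
# Jeffreys–Zellner–Siow Bayes factors


def jzs_bf10(t_stat: float, n: int, prior_scale: float = JZS_DEFAULT_SCALE) -> float:
    """Two-sided JZS BF10 for a one-sample t statistic (df = n − 1).

    Marginal likelihood under H1 integrates the non-central t likelihood
    over the Cauchy(0, prior_scale) effect-size prior; H0 is δ = 0.
    """
    if not np.isfinite(t_stat):
        raise ValueError("t statistic must be finite")
    nu = n - 1

    def integrand(delta):
        return stats.nct.pdf(t_stat, nu, delta * np.sqrt(n)) * stats.cauchy.pdf(delta, scale=prior_scale)

    m1, _ = quad(integrand, -np.inf, np.inf, limit=200)
    m0 = stats.t.pdf(t_stat, nu)
    return float(m1 / m0)


def _posterior_delta_samples(t_stat, n, prior_scale, n_samples, rng, grid_size=4001):
    """Sample effect sizes from the posterior of the two-sided JZS test via
    a dense grid + inverse-CDF draw."""
    nu = n - 1
    center = t_stat / np.sqrt(n)
    width = 10 / np.sqrt(n) + 3 * prior_scale
    grid = np.linspace(center - width, center + width, grid_size)
    dens = stats.nct.pdf(t_stat, nu, grid * np.sqrt(n)) * stats.cauchy.pdf(grid, scale=prior_scale)
    cdf = np.cumsum(dens)
    cdf /= cdf[-1]
    u = rng.random(n_samples)
    return grid[np.searchsorted(cdf, u)]


def one_sided_bf(
    t_stat: float,
    n: int,
    direction: str = "greater",
    prior_scale: float = JZS_DEFAULT_SCALE,
    n_samples: int = 1_000_000,
    seed: int = 0,
) -> BayesFactorResult:
    """One-sided JZS Bayes factor via posterior sampling.

    The two-sided BF10 is corrected by the posterior probability of the
    directional hypothesis divided by its prior probability (1/2 under the
    symmetric Cauchy prior): BF_one = BF_two × P(δ > 0 | data) / (1/2).
    ``direction='two_sided'`` returns the uncorrected BF. BF < 1/3 is the
    conventional threshold for substantial support of the null.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    bf2 = jzs_bf10(t_stat, n, prior_scale)
    if direction == "two_sided":
        return BayesFactorResult(bf10=bf2, direction=direction,
                                 posterior_samples_used=0, two_sided_bf10=bf2)
    if direction not in ("greater", "less"):
        raise ValueError(f"unknown direction {direction!r}")
    rng = np.random.default_rng(seed)
    samples = _posterior_delta_samples(t_stat, n, prior_scale, int(n_samples), rng)
    mass = float(np.mean(samples > 0) if direction == "greater" else np.mean(samples < 0))
    bf1 = bf2 * mass / 0.5
    return BayesFactorResult(bf10=float(bf1), direction=direction,
                             posterior_samples_used=int(n_samples), two_sided_bf10=bf2)


def session_model_interaction(fits: pd.DataFrame, alternative: str = "greater") -> dict:
    """Session × model interaction in per-session model fits.

    ``fits`` has columns session, model (two levels), value. The linear
    model value ~ session + model + session:model is fit by OLS and the
    interaction coefficient tested one-tailed with a conservative df of
    n_sessions − 2 (fits within a session share data). A reconstruction of
    the "did the fit trend toward one model" slope-comparison test.
    """
    models = sorted(fits["model"].unique())
    if len(models) != 2:
        raise ValueError("needs exactly 2 models")
    s = fits["session"].to_numpy(dtype=float)
    m = (fits["model"] == models[1]).to_numpy(dtype=float)
    s_c = s - s.mean()
    x = np.column_stack([np.ones(len(fits)), s_c, m, s_c * m])
    y = fits["value"].to_numpy(dtype=float)
    beta, ss_res = _ols(y, x)
    dof = fits["session"].nunique() - 2
    sigma2 = ss_res / max(len(y) - x.shape[1], 1)
    se = np.sqrt(sigma2 * np.linalg.inv(x.T @ x)[3, 3])
    t = beta[3] / se
    if alternative == "greater":
        p = stats.t.sf(t, dof)
    elif alternative == "less":
        p = stats.t.cdf(t, dof)
    else:
        p = 2 * stats.t.sf(abs(t), dof)
    return dict(interaction=float(beta[3]), t_stat=float(t), p_value=float(p), df=int(dof))
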