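"""Stability of the representational structure across runs and sessions.

Fits the distance-trend regression (finger pair + session + run) on
per-(session, run) RDMs, reports trend t-tests with conservative df,
Cohen's f² effect sizes, and one-sided Bayes factors; repeats the analysis
restricted to the high-confusion middle-ring / ring-pinky pairs, and runs
the session × model interaction on the per-session model fits.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np
import pandas as pd

from _common import MODEL_DIR, RESULTS, get_sessions
from neurorsa.compare import pair_covariance, wuc
from neurorsa.models import load_fixture_rdm, unstructured_rdm
from neurorsa.rdm import crossnobis
from neurorsa.spikes import bin_firing_rates
from neurorsa.stability import (
    fit_distance_trend,
    one_sided_bf,
    rdm_table,
    session_model_interaction,
    subset_trend,
)


def main():
    sessions = get_sessions()
    rdms, runs = [], []
    for s in sessions:
        cfg = s.config
        for run in np.unique(s.run_index):
            sel = s.run_index == run
            fr = bin_firing_rates(s.spike_counts[sel], (0.5, 1.5), cfg.bin_width,
                                  cfg.cue_time, labels=s.labels[sel])
            # 6 trials/condition per run: 3 folds keep >= 2 trials per fold
            rdms.append(crossnobis(fr.rates, fr.labels, n_folds=3, seed=0,
                                   session_index=s.session_index))
            runs.append(int(run))
    table = rdm_table(rdms, run_index=runs)

    fit = fit_distance_trend(table, alternative="greater")
    bf_sess = one_sided_bf(fit.t_session, n=fit.n_rdms, direction="greater", seed=0)
    bf_run = one_sided_bf(fit.t_run, n=fit.n_rdms, direction="greater", seed=1)
    print(f"all pairs ({fit.n_rdms} RDMs): "
          f"beta_session = {fit.beta_session:+.4f} (t({fit.df}) = {fit.t_session:.2f}, "
          f"one-tailed p = {fit.p_session:.2f}, f2 = {fit.f2_session:.4f}, BF = {bf_sess.bf10:.2f})")
    print(f"{'':18s}beta_run     = {fit.beta_run:+.4f} (t({fit.df}) = {fit.t_run:.2f}, "
          f"one-tailed p = {fit.p_run:.2f}, f2 = {fit.f2_run:.4f}, BF = {bf_run.bf10:.2f})")

    sub = subset_trend(table, ["M-R", "R-P"], alternative="greater")
    bf_sub = one_sided_bf(sub.t_session, n=sub.n_rdms, direction="greater", seed=2)
    print(f"high-confusion pairs (M-R, R-P): beta_session = {sub.beta_session:+.4f} "
          f"(one-tailed p = {sub.p_session:.2f}, BF = {bf_sub.bf10:.2f})")
    verdict = "supported (BF < 1/3)" if bf_sub.bf10 < 1 / 3 else "not resolved"
    print(f"  null hypothesis of no increase: {verdict}")

    # session x model interaction on per-session WUC fits
    vecs = np.stack([crossnobis(
        bin_firing_rates(s.spike_counts, (0.5, 1.5), s.config.bin_width,
                         s.config.cue_time, labels=s.labels).rates,
        s.labels, n_folds=5, seed=0).distances for s in sessions])
    v = pair_covariance(vecs)
    able = load_fixture_rdm(MODEL_DIR / "able_bodied_synthetic.csv").distances
    unst = unstructured_rdm().distances
    rows = []
    for i, vec in enumerate(vecs):
        rows.append(dict(session=i, model="able_bodied", value=wuc(vec, able, v).value))
        rows.append(dict(session=i, model="unstructured", value=wuc(vec, unst, v).value))
    inter = session_model_interaction(pd.DataFrame(rows), alternative="greater")
    print(f"session x model interaction: t({inter['df']}) = {inter['t_stat']:.2f}, "
          f"one-tailed p = {inter['p_value']:.2f}")

    out = dict(
        beta_session=fit.beta_session, beta_run=fit.beta_run, df=fit.df,
        p_session=fit.p_session, p_run=fit.p_run,
        f2_session=fit.f2_session, f2_run=fit.f2_run,
        bf_session=bf_sess.bf10, bf_run=bf_run.bf10,
        subset_beta_session=sub.beta_session, subset_p=sub.p_session,
        subset_bf=bf_sub.bf10, interaction=inter,
    )
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "stability.json", "w") as f:
        json.dump(out, f, indent=1)
    table.to_csv(RESULTS / "run_rdms.csv", index=False)
    print(f"wrote stability.json, run_rdms.csv")


if __name__ == "__main__":
    main()
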