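"""Finger decoding: diagonal LDA with LOO-CV per session, pooled confusion.

Reports per-session leave-one-out accuracy in the [0.5, 1.5]-s window
(low-rate electrodes excluded), the trial-weighted SD across sessions, and
the row-normalized confusion matrix pooled over sessions.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np
import pandas as pd

from _common import RESULTS, get_sessions, window_rates
from neurorsa.decoding import confusion, exclude_low_rate, loo_cv, pool_confusions, weighted_session_sd
from neurorsa.rdm import CONDITIONS


def main():
    sessions = get_sessions()
    rows, mats = [], []
    for s in sessions:
        fr = window_rates(s)
        mask = exclude_low_rate(fr.rates, min_rate=1.0)
        preds, acc = loo_cv(fr.rates[:, mask], fr.labels)
        rows.append(dict(session=s.session_index, n_trials=len(fr.labels),
                         n_features=int(mask.sum()), accuracy=acc))
        mats.append(confusion(fr.labels, preds, labels=list(CONDITIONS)))

    df = pd.DataFrame(rows)
    pooled = pool_confusions(mats)
    RESULTS.mkdir(exist_ok=True)
    df.to_csv(RESULTS / "decoding_accuracy.csv", index=False)
    pd.DataFrame(pooled.proportions, index=list(CONDITIONS),
                 columns=list(CONDITIONS)).to_csv(RESULTS / "confusion.csv")

    acc_pooled = pooled.accuracy
    sd = weighted_session_sd(df["accuracy"], df["n_trials"])
    print(df.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    print(f"\npooled LOO-CV accuracy: {acc_pooled:.1%} (weighted SD {sd:.1%}; chance 17%)")
    print("pooled confusion (rows = true):")
    print(pd.DataFrame(np.round(pooled.proportions, 2), index=list(CONDITIONS),
                       columns=list(CONDITIONS)).to_string())
    off = pooled.counts.copy()
    np.fill_diagonal(off, 0)
    idx = {c: i for i, c in enumerate(CONDITIONS)}
    adj = off[idx["M"], idx["R"]] + off[idx["R"], idx["M"]] + off[idx["R"], idx["P"]] + off[idx["P"], idx["R"]]
    print(f"middle-ring / ring-pinky confusions: {adj / max(off.sum(), 1):.0%} of all errors")
    print(f"wrote {RESULTS / 'decoding_accuracy.csv'}, {RESULTS / 'confusion.csv'}")


if __name__ == "__main__":
    main()
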