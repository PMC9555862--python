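"""Simulate the study-like synthetic dataset and write it to scratch/.

Generates 10 sessions of trial-structured Poisson spike counts whose
condition-mean geometry is a two-component mixture (muscle-like early,
somatotopic late, 0.17-s onset lag), and summarizes the dataset.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np

from _common import LAG, RESULTS, SCRATCH, get_sessions
from neurorsa.synth import save_session


def main():
    sessions = get_sessions()
    out = SCRATCH / "sessions"
    for s in sessions:
        save_session(s, out / f"session_{s.session_index:02d}")
    RESULTS.mkdir(exist_ok=True)

    n_trials = [len(s.labels) for s in sessions]
    n_units = [s.spike_counts.shape[1] for s in sessions]
    print(f"simulated {len(sessions)} sessions -> {out}")
    print(f"  trials/session: {np.mean(n_trials):.0f}, units/session: {np.mean(n_units):.0f}")
    print(f"  planted component lag: {LAG*1000:.0f} ms (muscle before somatotopy)")
    print(f"  clipped rate bins: {sum(s.clipped_rate_bins for s in sessions)}")
    counts = np.unique(sessions[0].labels, return_counts=True)
    print(f"  conditions balanced per session: {dict(zip(*counts))}")


if __name__ == "__main__":
    main()
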