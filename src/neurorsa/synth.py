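"""Synthetic trial-structured spike data with planted representational geometry.

The generator emulates the structure of an intracortical finger-movement
BCI experiment: ~96 units per session, 10 sessions of block-randomized
runs, 6 conditions (five fingers T/I/M/R/P plus a No-Go condition X),
3-second trials, Poisson spiking, and — crucially — condition-mean firing
rates whose pairwise geometry matches a user-specified target RDM, so that
every downstream estimator has a known ground truth. For representational-
dynamics testing, the condition means can be a time-varying mixture of two
component geometries with a configurable onset lag.

Rate model per (trial, neuron, time bin):

    rate(t) = baseline + Σ_components w_c(t − cue_time) · μ_c[condition, neuron]

with piecewise-linear onset ramps w_c(τ) (0 before onset, linear rise over
``rise_time``, then 1). Spike counts are Poisson(rate · bin_width) by
default; a Gaussian noise option (real-valued counts) exists for
closed-form oracle tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .rdm import CONDITIONS, matrix_to_rdm, rdm_to_matrix


@dataclass
class SessionConfig:
    n_neurons: int = 96
    n_sessions: int = 10
    runs_per_session: int = 8
    blocks_per_run: int = 4
    trials_per_block: int = 12  # two repetitions of each of the 6 conditions
    conditions: tuple[str, ...] = CONDITIONS
    trial_duration: float = 3.0
    cue_time: float = 0.5
    bin_width: float = 0.01
    baseline_rate: float = 5.0
    noise: str = "poisson"  # or "gaussian"
    gaussian_sd: float = 1.0  # rate SD (spikes/s) for the gaussian option
    seed: int = 0

    def __post_init__(self) -> None:
        self.conditions = tuple(self.conditions)
        if self.trials_per_block % len(self.conditions) != 0:
            raise ValueError("trials_per_block must be a multiple of the condition count")
        if not (self.trial_duration > self.cue_time >= 0):
            raise ValueError("need trial_duration > cue_time >= 0")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")

    @property
    def n_bins(self) -> int:
        return int(round(self.trial_duration / self.bin_width))

    @property
    def trials_per_session(self) -> int:
        return self.runs_per_session * self.blocks_per_run * self.trials_per_block

    @property
    def bin_times(self) -> np.ndarray:
        """Bin start times (s, relative to trial start)."""
        return np.arange(self.n_bins) * self.bin_width


@dataclass
class Component:
    """One geometry component: a target RDM plus its onset ramp."""

    name: str
    target_rdm: np.ndarray  # squared distances, conditions × conditions
    onset: float = 0.0      # s relative to cue
    rise_time: float = 0.2  # s, linear ramp duration

    def weight(self, peri_cue_time: np.ndarray) -> np.ndarray:
        t = np.asarray(peri_cue_time, dtype=float)
        if self.rise_time <= 0:
            return (t >= self.onset).astype(float)
        return np.clip((t - self.onset) / self.rise_time, 0.0, 1.0)


@dataclass
class GroundTruthGeometry:
    components: list[Component]
    component_lag: float = 0.0

    def __post_init__(self) -> None:
        for c in self.components:
            m = np.asarray(c.target_rdm, dtype=float)
            if m.ndim != 2 or not np.allclose(m, m.T) or np.any(np.diag(m) != 0):
                raise ValueError(f"component {c.name!r}: target_rdm must be symmetric, zero-diagonal")
            if np.any(m < 0):
                raise ValueError(f"component {c.name!r}: target_rdm entries must be non-negative")

    @property
    def target_rdm(self) -> np.ndarray:
        """Sum of component RDM matrices (the fully-mixed geometry is the
        pattern sum only when components occupy orthogonal subspaces, which
        the simulator arranges by seeding them independently; exact for a
        single component)."""
        return sum(np.asarray(c.target_rdm, dtype=float) for c in self.components)

    def weight_curves(self, peri_cue_time: np.ndarray) -> dict[str, np.ndarray]:
        return {c.name: c.weight(peri_cue_time) for c in self.components}


@dataclass
class SyntheticSession:
    spike_counts: np.ndarray  # trials × neurons × time bins
    labels: np.ndarray        # condition per trial
    run_index: np.ndarray     # per trial
    session_index: int
    config: SessionConfig
    ground_truth: GroundTruthGeometry
    condition_means: dict[str, np.ndarray] = field(default_factory=dict)
    clipped_rate_bins: int = 0
    waveforms: object | None = None


def build_condition_means(
    target_rdm: np.ndarray,
    n_neurons: int,
    seed: int = 0,
    baseline_rate: float = 0.0,
    tol: float = 1e-8,
) -> np.ndarray:
    """Invert an RDM into condition-mean rate offsets (conditions × neurons).

    Classical-scaling construction: the double-centered Gram matrix
    G = −½·C·D·C (C the centering matrix, D the target squared distances)
    is eigendecomposed; condition patterns are rows of V·√Λ, embedded into
    the neuron space by a seeded random rotation. Offsets are scaled so
    that pairwise squared Euclidean distances **divided by n_neurons**
    reproduce the target (matching the 1/N crossnobis normalization under
    identity noise), then shifted per neuron so baseline + offset ≥ 0.

    Raises ``ValueError`` naming the offending eigenvalue if the target is
    not embeddable (G not positive semi-definite).
    """
    d = np.asarray(target_rdm, dtype=float)
    n_cond = d.shape[0]
    matrix_to_rdm(d)  # validates symmetry / zero diagonal
    if np.any(d < 0):
        raise ValueError("target_rdm entries must be non-negative")
    c = np.eye(n_cond) - np.ones((n_cond, n_cond)) / n_cond
    gram = -0.5 * c @ (d * n_neurons) @ c
    eigval, eigvec = np.linalg.eigh(gram)
    scale = max(abs(eigval).max(), 1.0)
    if eigval.min() < -tol * scale:
        raise ValueError(
            f"target_rdm is not embeddable: Gram matrix has negative eigenvalue {eigval.min():.3e}"
        )
    eigval = np.clip(eigval, 0.0, None)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if np.sum(eigval > tol * scale) > n_neurons:
        raise ValueError(f"target_rdm needs rank > n_neurons={n_neurons} to embed")
    rank = min(n_cond, n_neurons)
    pattern = eigvec[:, :rank] * np.sqrt(eigval[:rank])  # conditions × rank
    # seeded random rotation into neuron space (orthonormal columns via QR)
    rng = np.random.default_rng(seed)
    q, r = np.linalg.qr(rng.standard_normal((n_neurons, rank)))
    q = q * np.sign(np.diag(r))
    means = pattern @ q.T  # conditions × neurons
    # per-neuron shift (constant across conditions => distances unchanged)
    shift = np.maximum(0.0, -(baseline_rate + means.min(axis=0)))
    return means + shift


def block_randomized_labels(config: SessionConfig, rng: np.random.Generator):
    """Trial labels and run indices with exact block randomization: every
    block of ``trials_per_block`` trials contains each condition equally often."""
    reps = config.trials_per_block // len(config.conditions)
    block = np.repeat(np.asarray(config.conditions, dtype=object), reps)
    labels, runs = [], []
    for run in range(config.runs_per_session):
        for _ in range(config.blocks_per_run):
            labels.append(rng.permutation(block))
            runs.append(np.full(config.trials_per_block, run))
    return np.concatenate(labels), np.concatenate(runs)


def simulate_session(
    config: SessionConfig,
    geometry: GroundTruthGeometry,
    session_index: int = 0,
    seed: int | None = None,
) -> SyntheticSession:
    """Draw one session of spike counts from the planted geometry.

    Each component RDM is embedded into condition-mean rate offsets with a
    component- and session-specific seed (so multi-component geometries
    occupy independent random subspaces), mixed with its onset ramp, added
    to the baseline rate, clipped at 0 (occurrences counted), and sampled
    as Poisson counts per bin. Fully reproducible given config/seed.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    labels, runs = block_randomized_labels(config, rng)
    cond_index = {c: i for i, c in enumerate(config.conditions)}

    peri = config.bin_times + 0.5 * config.bin_width - config.cue_time
    means = {}
    rate = np.zeros((len(labels), config.n_neurons, config.n_bins))
    for ci, comp in enumerate(geometry.components):
        mu = build_condition_means(
            comp.target_rdm, config.n_neurons, seed=seed * 997 + 13 * ci,
            baseline_rate=config.baseline_rate,
        )
        means[comp.name] = mu
        w = comp.weight(peri)  # n_bins
        trial_mu = mu[[cond_index[l] for l in labels]]  # trials × neurons
        rate += trial_mu[:, :, None] * w[None, None, :]
    rate += config.baseline_rate
    clipped = int(np.sum(rate < 0))
    if clipped:
        warnings.warn(f"{clipped} rate bins clipped at 0 after component mixing")
        rate = np.clip(rate, 0.0, None)

    lam = rate * config.bin_width
    if config.noise == "poisson":
        counts = rng.poisson(lam).astype(np.int32)
    elif config.noise == "gaussian":
        counts = lam + rng.standard_normal(lam.shape) * config.gaussian_sd * config.bin_width
    else:
        raise ValueError(f"unknown noise model {config.noise!r}")

    return SyntheticSession(
        spike_counts=counts,
        labels=labels,
        run_index=runs,
        session_index=session_index,
        config=config,
        ground_truth=geometry,
        condition_means=means,
        clipped_rate_bins=clipped,
    )


def simulate_dynamics(
    config: SessionConfig,
    modelA_rdm: np.ndarray,
    modelB_rdm: np.ndarray,
    lag: float = 0.170,
    onset_a: float = 0.15,
    rise_time: float = 0.2,
    session_index: int = 0,
    seed: int | None = None,
    names: tuple[str, str] = ("A", "B"),
) -> SyntheticSession:
    """Session whose geometry transitions: component A's ramp starts ``lag``
    seconds before component B's (default 170 ms)."""
    if lag < 0:
        raise ValueError("lag must be >= 0")
    if onset_a + lag >= config.trial_duration - config.cue_time:
        raise ValueError("lag places component B onset beyond the trial end")
    geometry = GroundTruthGeometry(
        components=[
            Component(names[0], np.asarray(modelA_rdm, float), onset=onset_a, rise_time=rise_time),
            Component(names[1], np.asarray(modelB_rdm, float), onset=onset_a + lag, rise_time=rise_time),
        ],
        component_lag=lag,
    )
    return simulate_session(config, geometry, session_index=session_index, seed=seed)


# ---------------------------------------------------------------------------
# waveform substrate for the spike-sorting stage


@dataclass
class WaveformSet:
    snippets: np.ndarray  # events × samples
    electrode_id: int = 0
    true_labels: np.ndarray | None = None


def _template(kind: int, n_samples: int) -> np.ndarray:
    """Stereotyped extracellular spike shapes (negative peak + rebound)."""
    t = np.linspace(0, 1, n_samples)
    trough = 0.25 + 0.08 * kind
    width = 0.05 + 0.02 * (kind % 3)
    shape = -np.exp(-((t - trough) ** 2) / (2 * width**2))
    shape += 0.35 * np.exp(-((t - trough - 0.25) ** 2) / (2 * (2 * width) ** 2))
    return shape / np.abs(shape).min() if shape.min() < 0 else shape


def simulate_waveforms(
    n_units_per_electrode: int,
    separation: float,
    seed: int = 0,
    n_events_per_unit: int = 200,
    n_samples: int = 48,
    noise_sd: float = 1.0,
    electrode_id: int = 0,
) -> WaveformSet:
    """Labeled Gaussian waveform clusters with known membership.

    Cluster means are distinct spike templates rescaled so consecutive
    clusters sit ``separation`` noise-SD units apart in snippet space
    (isotropic Gaussian noise, so Mahalanobis distance = Euclidean/σ).
    ``separation=0`` collapses all clusters onto one template.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    base = _template(0, n_samples) * 40.0
    snippets, labels = [], []
    for u in range(n_units_per_electrode):
        direction = _template(u + 1, n_samples) - base / 40.0
        direction /= np.linalg.norm(direction)
        mean = base + u * separation * noise_sd * direction
        ev = mean + rng.standard_normal((n_events_per_unit, n_samples)) * noise_sd
        snippets.append(ev)
        labels.append(np.full(n_events_per_unit, u))
    order = rng.permutation(n_units_per_electrode * n_events_per_unit)
    return WaveformSet(
        snippets=np.concatenate(snippets)[order],
        electrode_id=electrode_id,
        true_labels=np.concatenate(labels)[order],
    )


# ---------------------------------------------------------------------------
# session directory IO


def save_session(session: SyntheticSession, directory: str | Path) -> Path:
    """Write a session as a directory: HDF5 spike counts, CSV trial table,
    JSON config + ground truth."""
    import h5py
    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with h5py.File(directory / "spike_counts.h5", "w") as f:
        f.create_dataset("spike_counts", data=session.spike_counts, compression="gzip")
    pd.DataFrame(
        {"label": session.labels, "run_index": session.run_index}
    ).to_csv(directory / "trials.csv", index=False)
    meta = {
        "session_index": session.session_index,
        "config": asdict(session.config),
        "clipped_rate_bins": session.clipped_rate_bins,
        "ground_truth": {
            "component_lag": session.ground_truth.component_lag,
            "components": [
                {
                    "name": c.name,
                    "target_rdm": np.asarray(c.target_rdm).tolist(),
                    "onset": c.onset,
                    "rise_time": c.rise_time,
                }
                for c in session.ground_truth.components
            ],
        },
    }
    (directory / "session.json").write_text(json.dumps(meta, indent=1))
    return directory


def load_session(directory: str | Path) -> SyntheticSession:
    import h5py
    import pandas as pd

    directory = Path(directory)
    meta = json.loads((directory / "session.json").read_text())
    with h5py.File(directory / "spike_counts.h5", "r") as f:
        counts = f["spike_counts"][()]
    trials = pd.read_csv(directory / "trials.csv")
    cfg = meta["config"]
    cfg["conditions"] = tuple(cfg["conditions"])
    geometry = GroundTruthGeometry(
        components=[
            Component(c["name"], np.asarray(c["target_rdm"]), c["onset"], c["rise_time"])
            for c in meta["ground_truth"]["components"]
        ],
        component_lag=meta["ground_truth"]["component_lag"],
    )
    return SyntheticSession(
        spike_counts=counts,
        labels=trials["label"].to_numpy(dtype=object),
        run_index=trials["run_index"].to_numpy(),
        session_index=meta["session_index"],
        config=SessionConfig(**cfg),
        ground_truth=geometry,
        clipped_rate_bins=meta["clipped_rate_bins"],
    )
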