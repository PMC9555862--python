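"""Candidate model RDMs for the five-finger representational geometry.

Two parametric models are built here: a somatotopy model in which finger
activation patterns are linearly spaced Gaussian kernels on a notional 1-D
cortical sheet (neighboring fingers overlap, so their patterns are close),
and an unstructured model in which all fingers are pairwise equidistant
(the task-optimal null — the BCI task carries no between-finger
correlation). Usage/muscle/able-bodied matrices derive from external data
(kinematics, EMG, fMRI) and are consumed as fixture CSVs only; the
fixtures shipped with this repository are hand-constructed synthetic
stand-ins, not measured data.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .rdm import FINGERS, matrix_to_rdm, n_pairs, pair_labels, rdm_to_matrix


@dataclass
class ModelRDM:
    name: str
    distances: np.ndarray  # unique-pair vector, same order as data RDMs
    conditions: tuple[str, ...] = FINGERS
    normalization: str = "raw"  # raw | max_scaled | l2

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        self.conditions = tuple(self.conditions)
        if self.distances.shape != (n_pairs(len(self.conditions)),):
            raise ValueError("distance vector length does not match the condition count")

    @property
    def matrix(self) -> np.ndarray:
        return rdm_to_matrix(self.distances)


def normalize(rdm: ModelRDM, mode: str) -> ModelRDM:
    """Return a copy normalized per ``mode``; idempotent.

    max_scaled: max entry = 1 (as model RDMs are displayed);
    l2: unit vector norm (as required before NNLS decomposition so
    coefficient magnitudes are comparable).
    """
    v = rdm.distances
    if mode == "raw":
        return replace(rdm, normalization="raw")
    if mode == "max_scaled":
        m = np.abs(v).max()
        if m == 0:
            raise ValueError("cannot max-scale a zero RDM")
        return replace(rdm, distances=v / m, normalization="max_scaled")
    if mode == "l2":
        nrm = np.linalg.norm(v)
        if nrm == 0:
            raise ValueError("cannot l2-normalize a zero RDM")
        return replace(rdm, distances=v / nrm, normalization="l2")
    raise ValueError(f"unknown normalization mode {mode!r}")


def somatotopy_rdm(n_fingers: int = 5, kernel_sd: float = 1.0) -> ModelRDM:
    """Somatotopy model: fingers at integer positions 1..n on a 1-D sheet,
    each activating a unit-norm Gaussian kernel of width ``kernel_sd``.

    For L2-normalized Gaussian kernels the squared pattern distance has
    the closed form d²(i, j) = 2 − 2·exp(−(i−j)² / (4·kernel_sd²)).
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be positive")
    pos = np.arange(1, n_fingers + 1, dtype=float)
    diff = pos[:, None] - pos[None, :]
    mat = 2.0 - 2.0 * np.exp(-(diff**2) / (4.0 * kernel_sd**2))
    np.fill_diagonal(mat, 0.0)
    conds = FINGERS if n_fingers == 5 else tuple(f"F{i}" for i in range(1, n_fingers + 1))
    return ModelRDM("somatotopy", matrix_to_rdm(mat), conditions=conds)


def unstructured_rdm(n_fingers: int = 5) -> ModelRDM:
    """Pairwise-equidistant (unstructured) model, max-scaled to 1."""
    conds = FINGERS if n_fingers == 5 else tuple(f"F{i}" for i in range(1, n_fingers + 1))
    return ModelRDM("unstructured", np.ones(n_pairs(n_fingers)), conditions=conds,
                    normalization="max_scaled")


def load_fixture_rdm(path: str | Path, name: str | None = None) -> ModelRDM:
    """Load a model RDM from CSV: either a 5×5 symmetric zero-diagonal
    matrix with a finger-label header (T,I,M,R,P) or a single 10-vector
    row in the standard pair order."""
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    name = name or path.stem
    values = df.to_numpy(dtype=float)
    if values.shape == (5, 5):
        cols = tuple(str(c).strip() for c in df.columns)
        if cols != FINGERS:
            raise ValueError(f"expected finger header {FINGERS}, got {cols}")
        if not np.allclose(values, values.T):
            bad = np.argwhere(~np.isclose(values, values.T))
            raise ValueError(f"fixture matrix is asymmetric at entries {bad.tolist()}")
        return ModelRDM(name, matrix_to_rdm(values))
    flat = values.ravel()
    if flat.shape == (10,):
        return ModelRDM(name, flat)
    raise ValueError(f"fixture must be a 5×5 matrix or 10-vector, got shape {values.shape}")


def save_fixture_rdm(rdm: ModelRDM, path: str | Path) -> None:
    pd.DataFrame(rdm.matrix, index=list(rdm.conditions), columns=list(rdm.conditions)).to_csv(path)


def with_no_go(rdm: ModelRDM | np.ndarray) -> np.ndarray:
    """Extend a 5-finger RDM to the 6 task conditions for simulation.

    The No-Go condition carries no movement-specific tuning, so its pattern
    is placed at the centroid of the finger patterns (recovered by
    classical scaling of the finger RDM). Returns a 6×6 squared-distance
    matrix ordered (T, I, M, R, P, X); exactly embeddable by construction.
    """
    mat = rdm.matrix if isinstance(rdm, ModelRDM) else rdm_to_matrix(np.asarray(rdm, float))
    n = mat.shape[0]
    c = np.eye(n) - np.ones((n, n)) / n
    gram = -0.5 * c @ mat @ c
    eigval, eigvec = np.linalg.eigh(gram)
    pats = eigvec * np.sqrt(np.clip(eigval, 0.0, None))  # centered: centroid at 0
    pats6 = np.vstack([pats, np.zeros(n)])
    d = ((pats6[:, None, :] - pats6[None, :, :]) ** 2).sum(axis=2)
    np.fill_diagonal(d, 0.0)
    return d


def surrogate_structured_rdm(
    distinctness: np.ndarray | list[float],
    seed: int = 0,
    name: str = "surrogate",
) -> ModelRDM:
    """Random embeddable RDM with a controlled per-finger distinctness
    profile: finger patterns are seeded Gaussian vectors scaled by
    ``distinctness``, so larger-scale fingers sit farther from the rest.
    Useful as a test-only stand-in for structured external models."""
    scales = np.asarray(distinctness, dtype=float)
    rng = np.random.default_rng(seed)
    pats = rng.standard_normal((len(scales), max(4, len(scales)))) * scales[:, None]
    d = ((pats[:, None, :] - pats[None, :, :]) ** 2).sum(axis=2)
    conds = FINGERS if len(scales) == 5 else tuple(f"F{i}" for i in range(1, len(scales) + 1))
    return ModelRDM(name, matrix_to_rdm(d), conditions=conds)
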