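"""Finger classification with diagonal-covariance LDA.

Diagonal LDA pools a single per-feature variance across classes, which
makes it identical to Gaussian naive Bayes under a shared covariance — a
useful regularization when trials are few and units are many. Electrodes
(features) with session-mean firing rates below 1 Hz are excluded before
fitting; accuracy is evaluated with leave-one-out cross-validation within
each session, and confusion matrices are row-normalized by true label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spikes import FiringRateMatrix, bin_firing_rates

VAR_FLOOR = 1e-6  # spikes²/s², avoids division by zero for silent features


@dataclass
class DiagLdaModel:
    classes: np.ndarray
    class_means: np.ndarray      # classes × features
    pooled_variances: np.ndarray  # per feature, shared across classes
    priors: np.ndarray
    included_features: np.ndarray  # boolean mask over the original features

    def log_posterior(self, x: np.ndarray) -> np.ndarray:
        """Unnormalized Gaussian log-posterior per class (rows = samples)."""
        x = np.atleast_2d(np.asarray(x, dtype=float))[:, self.included_features]
        diff = x[:, None, :] - self.class_means[None, :, :]
        ll = -0.5 * (diff**2 / self.pooled_variances).sum(axis=2)
        ll -= 0.5 * np.log(2 * np.pi * self.pooled_variances).sum()
        return ll + np.log(self.priors)

    def predict(self, x: np.ndarray) -> np.ndarray:
        # argmax with lowest-class-index tie-break (np.argmax is first-max)
        return self.classes[np.argmax(self.log_posterior(x), axis=1)]


def exclude_low_rate(rates: np.ndarray, min_rate: float = 1.0) -> np.ndarray:
    """Mask of features whose session-mean rate is >= min_rate (strictly
    below 1 Hz is excluded, boundary inclusive)."""
    mask = np.asarray(rates, dtype=float).mean(axis=0) >= min_rate
    if not mask.any():
        raise ValueError(f"all features fall below the {min_rate} Hz floor")
    return mask


def fit_diag_lda(
    features: FiringRateMatrix | np.ndarray,
    labels: np.ndarray | None = None,
    priors: np.ndarray | None = None,
    min_rate: float | None = 1.0,
    var_floor: float = VAR_FLOOR,
) -> DiagLdaModel:
    """Fit diagonal LDA on trial × feature firing rates.

    The per-feature variance is pooled across classes (residuals around
    each class mean, ddof = n − n_classes) and floored. Priors default to
    uniform (the task block-randomizes conditions). Features below the
    ``min_rate`` floor are excluded first (pass None to skip).
    """
    if isinstance(features, FiringRateMatrix):
        x, y = features.rates, features.labels
    else:
        x, y = np.asarray(features, dtype=float), labels
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(y_idx)
    if counts.min() < 2:
        missing = classes[counts < 2]
        raise ValueError(f"classes with fewer than 2 training trials: {list(missing)}")

    mask = exclude_low_rate(x, min_rate) if min_rate is not None else np.ones(x.shape[1], bool)
    xm = x[:, mask]
    means = np.stack([xm[y_idx == i].mean(axis=0) for i in range(len(classes))])
    resid = xm - means[y_idx]
    pooled = (resid**2).sum(axis=0) / (len(y) - len(classes))
    pooled = np.maximum(pooled, var_floor)
    priors = np.full(len(classes), 1 / len(classes)) if priors is None else np.asarray(priors, float)
    return DiagLdaModel(classes, means, pooled, priors / priors.sum(), mask)


def loo_cv(
    features: np.ndarray,
    labels: np.ndarray,
    model_factory=None,
) -> tuple[np.ndarray, float]:
    """Leave-one-out cross-validation: each trial predicted by a model
    trained on all the others. Returns (predictions, accuracy)."""
    x = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(y) < 2:
        raise ValueError("need at least 2 trials")
    if model_factory is None:
        model_factory = lambda xt, yt: fit_diag_lda(xt, yt, min_rate=None)
    preds = np.empty(len(y), dtype=y.dtype)
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        model = model_factory(x[keep], y[keep])
        preds[i] = model.predict(x[i : i + 1])[0]
    return preds, float(np.mean(preds == y))


def select_window(
    spike_counts: np.ndarray,
    labels: np.ndarray,
    candidate_windows: list[tuple[float, float]],
    bin_width: float,
    cue_time: float = 0.0,
    min_rate: float = 1.0,
) -> tuple[float, float]:
    """Pick the analysis window maximizing LOO-CV accuracy on calibration
    data; ties go to the earliest window."""
    if len(candidate_windows) < 2:
        raise ValueError("need at least 2 candidate windows")
    best, best_acc = None, -1.0
    for win in sorted(candidate_windows, key=lambda w: w[0]):
        fr = bin_firing_rates(spike_counts, win, bin_width, cue_time, labels=labels)
        try:
            mask = exclude_low_rate(fr.rates, min_rate)
        except ValueError:
            continue
        _, acc = loo_cv(fr.rates[:, mask], labels)
        if acc > best_acc:  # strict: earliest wins ties
            best, best_acc = win, acc
    return best


@dataclass
class ConfusionMatrix:
    labels: np.ndarray
    counts: np.ndarray        # true × predicted
    proportions: np.ndarray   # rows normalized by true-label count
    empty_rows: np.ndarray    # flags rows with zero trials

    @property
    def accuracy(self) -> float:
        return float(np.trace(self.counts) / self.counts.sum())


def confusion(y_true, y_pred, labels=None) -> ConfusionMatrix:
    """Row-normalized confusion matrix: entry (i, j) is the proportion of
    true-class-i trials predicted as class j."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    if labels is None:
        labels = np.unique(np.concatenate([y_true, y_pred]))
    labels = np.asarray(labels)
    unseen = set(y_pred) - set(labels)
    if unseen or set(y_true) - set(labels):
        raise ValueError(f"labels not in the provided class list: {unseen or set(y_true) - set(labels)}")
    idx = {c: i for i, c in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[p]] += 1
    row = counts.sum(axis=1)
    empty = row == 0
    props = np.divide(counts, np.where(empty, 1, row)[:, None], dtype=float)
    props[empty] = 0.0
    return ConfusionMatrix(labels=labels, counts=counts, proportions=props, empty_rows=empty)


def pool_confusions(matrices: list[ConfusionMatrix]) -> ConfusionMatrix:
    """Aggregate across sessions by pooling trial counts before normalizing."""
    labels = matrices[0].labels
    counts = sum(m.counts for m in matrices)
    row = counts.sum(axis=1)
    empty = row == 0
    props = np.divide(counts, np.where(empty, 1, row)[:, None], dtype=float)
    props[empty] = 0.0
    return ConfusionMatrix(labels=labels, counts=counts, proportions=props, empty_rows=empty)


def weighted_session_sd(values: np.ndarray, weights: np.ndarray) -> float:
    """SD across sessions weighted by per-session trial counts."""
    values, weights = np.asarray(values, float), np.asarray(weights, float)
    mean = np.average(values, weights=weights)
    return float(np.sqrt(np.average((values - mean) ** 2, weights=weights)))
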