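"""Time-resolved touch-type decoding with diagonal-covariance LDA.

The classifier is Gaussian linear discriminant analysis under two
assumptions: class distributions differ only in their means (one pooled
covariance), and units are independent (the pooled covariance is
diagonal).  Equal class priors are used (the design is balanced).
Performance is the prediction accuracy of stratified leave-one-out
cross-validation, computed per session and averaged across sessions, in
sliding 300 ms windows stepped at 10 ms from 0.5 s before stimulation
onset.  All recorded units enter the classifier (no preselection of
modulated units, to avoid peeking).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import SpikeCountTensor, snap_window

#: variance floor for units silent in a window (Hz^2)
VAR_EPS = 1e-6


@dataclass
class DiagLDA:
    """Shared-diagonal-covariance Gaussian classifier state."""

    classes: np.ndarray       # sorted class labels (canonical tie-break order)
    means: np.ndarray         # classes x features
    var: np.ndarray           # pooled within-class diagonal variance, floored

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Log-likelihood scores (equal priors, constants dropped)."""
        X = np.atleast_2d(X)
        # -(x - mu)^2 / (2 var) summed over features
        d = X[:, None, :] - self.means[None, :, :]
        return -0.5 * (d * d / self.var[None, None, :]).sum(axis=2)

    def predict(self, X: np.ndarray) -> np.ndarray:
        s = self.scores(X)
        return self.classes[np.argmax(s, axis=1)]  # ties -> first class


def train_diag_lda(X: np.ndarray, y: np.ndarray) -> DiagLDA:
    """Fit per-class means and one pooled diagonal variance.

    The pooled variance is the within-class variance averaged over all
    trials (biased/MLE pooling), floored at ``VAR_EPS`` per feature so
    that units silent in a window do not produce infinities.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    resid = X - means[np.searchsorted(classes, y)]
    var = np.maximum((resid ** 2).mean(axis=0), VAR_EPS)
    return DiagLDA(classes, means, var)


def loocv_accuracy(X: np.ndarray, y: np.ndarray) -> float:
    """Stratified leave-one-out accuracy of the diagonal LDA.

    Each trial is held out once and the classifier refit on the rest;
    LOO over a class-balanced set is inherently stratified.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    n = len(y)
    correct = 0
    idx = np.arange(n)
    for i in range(n):
        train = idx != i
        clf = train_diag_lda(X[train], y[train])
        correct += int(clf.predict(X[i:i + 1])[0] == y[i])
    return correct / n


@dataclass
class DecodingCurve:
    window_starts: np.ndarray
    accuracy: np.ndarray      # sessions x windows
    classes: list
    window: float
    step: float

    @property
    def chance(self) -> float:
        return 1.0 / len(self.classes)

    def summary(self) -> pd.DataFrame:
        acc = np.atleast_2d(self.accuracy)
        n = acc.shape[0]
        mean = acc.mean(axis=0)
        if n > 1:
            sem = acc.std(axis=0, ddof=1) / np.sqrt(n)
            crit = stats.t.ppf(0.975, n - 1)
        else:
            sem, crit = np.zeros_like(mean), 0.0
        return pd.DataFrame({
            "window_start": self.window_starts,
            "accuracy": mean,
            "ci_lo": mean - crit * sem,
            "ci_hi": mean + crit * sem,
        })


def window_starts(start: float = -0.5, stop: float = 3.0, step: float = 0.01
                  ) -> np.ndarray:
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def session_curve(tensor: SpikeCountTensor, field: str | None = None,
                  window: float = 0.3, step: float = 0.01,
                  start: float = -0.5, stop: float = 3.0) -> np.ndarray:
    """LOO decoding accuracy of touch type per window for one session.

    ``field`` restricts trials to one sensory field (Ac/As/Oc/Os); the
    four touch types are the decoded classes.  Windows whose end exceeds
    coverage are dropped (truncated curve).
    """
    if field is not None:
        keep = np.array([i for i, l in enumerate(tensor.trial_labels)
                         if l.sensory_field == field])
        tensor = tensor.subset_trials(keep)
    y = np.array([l.touch_type for l in tensor.trial_labels])
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 touch-type classes to decode")
    starts = window_starts(start, stop, step)
    starts = starts[starts + window <= tensor.bin_edges[-1] + 1e-9]
    acc = np.empty(len(starts))
    for w, s in enumerate(starts):
        lo, hi = snap_window((s, s + window), tensor.bin_edges)
        dur = tensor.bin_edges[hi] - tensor.bin_edges[lo]
        X = tensor.counts[:, :, lo:hi].sum(axis=2).T / dur  # trials x units
        acc[w] = loocv_accuracy(X, y)
    return acc


def time_resolved_accuracy(sessions: list[SpikeCountTensor],
                           field: str = "Ac", window: float = 0.3,
                           step: float = 0.01, start: float = -0.5,
                           stop: float = 3.0) -> DecodingCurve:
    """Touch-type decoding curve within one sensory field, across sessions."""
    curves = [session_curve(t, field, window, step, start, stop)
              for t in sessions]
    starts = window_starts(start, stop, step)
    n = min(len(c) for c in curves)
    return DecodingCurve(starts[:n], np.vstack([c[:n] for c in curves]),
                         classes=sorted({l.touch_type
                                         for l in sessions[0].trial_labels}),
                         window=window, step=step)
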