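"""Population-level response-strength and similarity metrics.

Two summaries of a session's population response:

* a *discriminability index* (DI) between the stimulation-window and
  baseline-window population rate vectors,

      DI = (mean(A) - mean(B)) / sqrt((var(A) + var(B)) / 2),

  where A concatenates every unit's mean rate for a condition over the
  analysis window and B the same over the 1 s pre-stimulus baseline;

* a *split-half cross-validated correlation matrix*: per resample, the
  trials of every condition are split 50/50, per-condition population
  rate vectors are averaged within each half, and half-1 of condition i
  is Pearson-correlated with half-2 of condition j.  The within-condition
  diagonal estimates the reliability ceiling of the similarity measure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    ConditionLabel,
    SpikeCountTensor,
    TrialTimeline,
    window_rate,
)


def di_formula(a: np.ndarray, b: np.ndarray) -> float:
    """The printed standardized-difference formula on two rate vectors."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    num = a.mean() - b.mean()
    denom = np.sqrt((a.var(ddof=0) + b.var(ddof=0)) / 2.0)
    if denom == 0.0:
        if num == 0.0:
            return 0.0
        raise ValueError("DI undefined: both vectors constant but unequal")
    return float(num / denom)


def discriminability_index(tensor: SpikeCountTensor,
                           condition: ConditionLabel,
                           timeline: TrialTimeline | None = None) -> float:
    """DI of one condition's population response vs. baseline (one session)."""
    if tensor.n_units < 2:
        raise ValueError("DI needs at least 2 units")
    timeline = timeline or tensor.timeline
    idx = tensor.trials_of(condition)
    resp = window_rate(tensor, timeline.analysis_window)[:, idx].mean(axis=1)
    base = window_rate(tensor, timeline.baseline_window)[:, idx].mean(axis=1)
    return di_formula(resp, base)


def di_summary(sessions: list[SpikeCountTensor],
               timeline: TrialTimeline | None = None
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """DI per condition/session plus a mean and 95% CI summary across sessions."""
    rows = []
    for tensor in sessions:
        for c in tensor.conditions():
            rows.append({
                "condition": f"{c.sensory_field}:{c.touch_type}",
                "session": tensor.session_id,
                "di": discriminability_index(tensor, c, timeline),
            })
    df = pd.DataFrame(rows)
    g = df.groupby("condition")["di"]
    n = g.count()
    sem = g.std(ddof=1) / np.sqrt(n)
    crit = stats.t.ppf(0.975, np.maximum(n - 1, 1))
    summary = pd.DataFrame({
        "mean": g.mean(), "ci_lo": g.mean() - crit * sem,
        "ci_hi": g.mean() + crit * sem,
    }).reset_index()
    return df, summary


def crossval_mahalanobis_di(tensor: SpikeCountTensor, condition: ConditionLabel,
                            timeline: TrialTimeline | None = None,
                            shrinkage: float = 0.1) -> float:
    """Alternative multivariate distance: leave-one-trial-out Mahalanobis.

    Cross-validated (crossnobis-style) squared Mahalanobis distance
    between stimulation and baseline trial ensembles under a
    shrinkage-regularized diagonal-blended covariance; returned as the
    signed square root.  Provided as a flagged alternative to the
    univariate formula; the printed formula is the default everywhere.
    """
    timeline = timeline or tensor.timeline
    idx = tensor.trials_of(condition)
    A = window_rate(tensor, timeline.analysis_window)[:, idx].T  # trials x units
    B = window_rate(tensor, timeline.baseline_window)[:, idx].T
    n = A.shape[0]
    X = np.vstack([A - A.mean(0), B - B.mean(0)])
    cov = X.T @ X / (X.shape[0] - 2)
    cov = (1 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
    cov += 1e-9 * np.eye(cov.shape[0])
    d2 = 0.0
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        d_train = A[rest].mean(0) - B[rest].mean(0)
        d_test = A[i] - B[i]
        d2 += d_train @ np.linalg.solve(cov, d_test)
    d2 /= n
    return float(np.sign(d2) * np.sqrt(abs(d2)))


# ---------------------------------------------------------------------------
# split-half correlation


@dataclass
class CorrelationMatrix:
    conditions: list[ConditionLabel]
    r: np.ndarray             # conditions x conditions, resample-averaged
    n_resamples: int

    def to_frame(self) -> pd.DataFrame:
        names = [f"{c.sensory_field}:{c.touch_type}" for c in self.conditions]
        return pd.DataFrame(self.r, index=names, columns=names)


def splithalf_correlation(tensor: SpikeCountTensor,
                          timeline: TrialTimeline | None = None,
                          n_resamples: int = 250, seed: int = 0
                          ) -> CorrelationMatrix:
    """Split-half cross-validated condition-pair correlation matrix.

    Odd trial counts are split ceil/floor, alternating which half is
    larger across resamples.  The returned matrix is symmetrized by
    averaging r(i half1, j half2) with r(j half1, i half2).
    """
    timeline = timeline or tensor.timeline
    rng = np.random.default_rng(seed)
    rates = window_rate(tensor, timeline.analysis_window)  # units x trials
    conds = tensor.conditions()
    trials = [tensor.trials_of(c) for c in conds]
    for c, idx in zip(conds, trials):
        if len(idx) < 2:
            raise ValueError(f"condition {c} has fewer than 2 trials")
    k = len(conds)
    acc = np.zeros((k, k))
    for rep in range(n_resamples):
        h1 = np.empty((tensor.n_units, k))
        h2 = np.empty((tensor.n_units, k))
        for j, idx in enumerate(trials):
            perm = rng.permutation(idx)
            n_half = (len(idx) + (rep % 2)) // 2  # alternate ceil/floor
            h1[:, j] = rates[:, perm[:n_half]].mean(axis=1)
            h2[:, j] = rates[:, perm[n_half:]].mean(axis=1)
        c = np.corrcoef(np.hstack([h1, h2]).T)[:k, k:]
        acc += (c + c.T) / 2.0
    return CorrelationMatrix(conds, acc / n_resamples, n_resamples)


def within_between_test(values_matched: np.ndarray,
                        values_mismatched: np.ndarray) -> tuple[float, float]:
    """Two-sample t-test comparing matched vs. mismatched pair correlations.

    Inputs are session-level correlation values (e.g. same-body-part
    pairs vs. different-body-part pairs across persons).  Returns (t, p).
    """
    a = np.asarray(values_matched, float)
    b = np.asarray(values_mismatched, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both pair sets must be non-empty")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        raise ValueError("degenerate zero-variance samples with unequal means")
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def matched_mismatched_pairs(conds: list[ConditionLabel]
                             ) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Across-person condition pairs split by body-part match.

    Matched: same body part (and same touch type), actual vs. observed.
    Mismatched: different body part (same touch type), actual vs. observed.
    """
    matched, mismatched = [], []
    for i, ci in enumerate(conds):
        for j, cj in enumerate(conds):
            if ci.person == "actual" and cj.person == "observed" \
                    and ci.touch_type == cj.touch_type:
                (matched if ci.body_part == cj.body_part else mismatched
                 ).append((i, j))
    return matched, mismatched
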