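"""Per-neuron condition tuning: linear model, FDR, responsive fractions,
and event-related averages.

A unit's response is the mean rate over the analysis window (0.5 s after
stimulus onset to 0.5 s after offset), measured relative to its 1 s
pre-stimulus baseline, and regressed on condition indicators

    FR = sum_c beta_c * X_c + beta_0,

with a zero-intercept reference: beta_c is the unit's modulation from
baseline in condition c.  A unit is responsive to a condition if the
t-statistic of beta_c is significant at P < 0.05, Benjamini-Hochberg FDR
corrected across the conditions of that unit (two-sided, so suppression
counts as modulation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data_model import (
    ConditionLabel,
    SpikeCountTensor,
    TrialTimeline,
    snap_window,
    window_rate,
)


@dataclass
class TuningFit:
    """OLS condition tuning of one unit (baseline-referenced)."""

    conditions: list[ConditionLabel]
    beta: np.ndarray        # Hz modulation from baseline, per condition
    tstat: np.ndarray
    pvalue: np.ndarray
    significant: np.ndarray  # BH-FDR mask at q
    q: float = 0.05


def fdr_correct(pvalues: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(pvalues, alpha=q, method="fdr_bh")
    return reject


def fit_condition_model(rates: np.ndarray, labels: list[ConditionLabel],
                        baseline_rates: np.ndarray, q: float = 0.05
                        ) -> TuningFit:
    """Fit the indicator model to one unit's per-trial rates.

    With one indicator per condition and no shared intercept, each
    beta_c is the mean baseline-subtracted rate in condition c, and its
    t-statistic the usual OLS coefficient test (pooled residual
    variance).  Requires >= 2 trials in every condition.
    """
    y = np.asarray(rates, float) - np.asarray(baseline_rates, float)
    conds = sorted(set(labels))
    counts = {c: labels.count(c) for c in conds}
    thin = [c for c, n in counts.items() if n < 2]
    if thin:
        raise ValueError(f"conditions with fewer than 2 trials: {thin}")
    X = np.column_stack([[1.0 if l == c else 0.0 for l in labels] for c in conds])
    n, k = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = n - k
    sigma2 = resid @ resid / dof
    se = np.sqrt(sigma2 / np.diag(X.T @ X))
    # exact fits (zero residual variance): t is +/-inf for nonzero beta, 0 else
    t = beta / np.where(se > 0, se, 1.0)
    exact = se == 0
    t[exact & (beta > 0)] = np.inf
    t[exact & (beta < 0)] = -np.inf
    t[exact & (beta == 0)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), dof)
    return TuningFit(conds, beta, t, p, fdr_correct(p, q), q)


def fit_session(tensor: SpikeCountTensor, timeline: TrialTimeline | None = None,
                q: float = 0.05) -> list[TuningFit]:
    """Tuning fit for every unit of a session."""
    timeline = timeline or tensor.timeline
    resp = window_rate(tensor, timeline.analysis_window)
    base = window_rate(tensor, timeline.baseline_window)
    return [fit_condition_model(resp[u], tensor.trial_labels, base[u], q)
            for u in range(tensor.n_units)]


def fraction_responsive(fits_per_session: list[list[TuningFit]],
                        n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-condition fraction of responsive units, with 95% CI.

    Proportions are computed per session; the point estimate is their
    mean and the CI a seeded percentile bootstrap across sessions.
    """
    if not fits_per_session:
        raise ValueError("no sessions")
    conds = fits_per_session[0][0].conditions
    per_session = np.array([
        [np.mean([f.significant[j] for f in fits]) for j in range(len(conds))]
        for fits in fits_per_session
    ])  # sessions x conditions
    rng = np.random.default_rng(seed)
    n_sess = per_session.shape[0]
    boots = per_session[rng.integers(n_sess, size=(n_boot, n_sess))].mean(axis=1)
    lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "condition": [f"{c.sensory_field}:{c.touch_type}" for c in conds],
        "fraction": per_session.mean(axis=0),
        "ci_lo": lo,
        "ci_hi": hi,
    })


def event_related_average(tensor: SpikeCountTensor, window: float = 0.75,
                          step: float = 0.1, span: tuple[float, float] = (-0.5, 2.5)
                          ) -> pd.DataFrame:
    """Windowed mean rate (Hz) +/- SEM per condition and window start.

    Defaults follow the published display convention: 750 ms windows
    stepped at 100 ms, window starts from 0.5 s before stimulation onset
    through 2.5 s after (31 starts).
    """
    starts = span[0] + step * np.arange(int(round((span[1] - span[0]) / step)) + 1)
    if starts[0] < tensor.bin_edges[0] or starts[-1] + window > tensor.bin_edges[-1]:
        raise ValueError(f"span {span} (+{window} s window) outside coverage")
    conds = tensor.conditions()
    rows = []
    for start in starts:
        lo, hi = snap_window((start, start + window), tensor.bin_edges)
        dur = tensor.bin_edges[hi] - tensor.bin_edges[lo]
        rate = tensor.counts[:, :, lo:hi].sum(axis=2) / dur  # units x trials
        for c in conds:
            r = rate[:, tensor.trials_of(c)]
            n = r.shape[1]
            rows.append({
                "condition": f"{c.sensory_field}:{c.touch_type}",
                "window_start": float(start),
                "mean": r.mean(),
                "sem": r.mean(axis=0).std(ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            })
    return pd.DataFrame(rows)
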