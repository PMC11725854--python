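"""Population-subspace generalization across task contexts.

Two complementary analyses probe whether the population code is built
from generalizable building blocks:

* **Demixed latent subspaces** — on a training context (one level of a
  held-out dimension, e.g. actual touch only), condition-mean responses
  are decomposed into marginal components per factor (body part, touch
  type, and their interaction), and a low-rank linear readout (encoder/
  decoder pair) is fit per marginalization in the demixed-PCA style
  (marginalized covariance + ridge-regularized low-rank regression).
  The learned mapping is then applied to the other context's held-out
  data; if the factor's latent levels still separate, the building block
  generalizes.

* **Discrimination-axis transfer** — a linear axis discriminating two
  conditions is learned in the training context (variance-whitened mean
  difference; diagonal-covariance LDA direction), and the distance
  between the corresponding pair of test-context conditions along that
  axis is divided by the training-context distance.  1 means full
  transfer, 0 none.  Both distances are estimated with split-half
  cross-validation (independent halves on each side of the product), so
  pure-noise data concentrate near 0 rather than being inflated by
  overfitting.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import (
    BODY_PARTS,
    PERSONS,
    TOUCH_TYPES,
    ConditionLabel,
    SpikeCountTensor,
    snap_window,
)

FACTOR_LEVELS = {
    "person": PERSONS,
    "body_part": BODY_PARTS,
    "touch_type": TOUCH_TYPES,
}


def sliding_windows(window: float = 0.75, step: float = 0.1,
                    span: tuple[float, float] = (-0.5, 2.5)
                    ) -> list[tuple[float, float]]:
    starts = span[0] + step * np.arange(int(round((span[1] - span[0]) / step)) + 1)
    return [(float(s), float(s + window)) for s in starts]


def _window_rates(tensor: SpikeCountTensor,
                  windows: list[tuple[float, float]]) -> np.ndarray:
    """units x trials x windows rate array (Hz)."""
    out = np.empty((tensor.n_units, tensor.n_trials, len(windows)))
    for w, win in enumerate(windows):
        lo, hi = snap_window(win, tensor.bin_edges)
        dur = tensor.bin_edges[hi] - tensor.bin_edges[lo]
        out[:, :, w] = tensor.counts[:, :, lo:hi].sum(axis=2) / dur
    return out


# ---------------------------------------------------------------------------
# marginalization (exact two-way decomposition)


def marginalize(M: np.ndarray) -> dict[str, np.ndarray]:
    """Decompose a units x n1 x n2 x windows condition-mean tensor.

    Returns additive components (each broadcast to M's shape) keyed
    'grand', 'factor1', 'factor2', 'interaction'.  On a balanced design
    the components are mutually orthogonal and sum back to M exactly.
    """
    grand = M.mean(axis=(1, 2), keepdims=True)
    f1 = M.mean(axis=2, keepdims=True) - grand
    f2 = M.mean(axis=1, keepdims=True) - grand
    inter = M - grand - f1 - f2
    return {
        "grand": np.broadcast_to(grand, M.shape).copy(),
        "factor1": np.broadcast_to(f1, M.shape).copy(),
        "factor2": np.broadcast_to(f2, M.shape).copy(),
        "interaction": inter,
    }


def condition_mean_tensor(tensor: SpikeCountTensor, fixed: dict[str, str],
                          factor1: str, factor2: str,
                          windows: list[tuple[float, float]],
                          trial_subset: np.ndarray | None = None) -> np.ndarray:
    """units x levels1 x levels2 x windows condition means within a context."""
    rates = _window_rates(tensor, windows)
    if trial_subset is not None:
        rates = rates[:, trial_subset]
        labels = [tensor.trial_labels[i] for i in trial_subset]
    else:
        labels = tensor.trial_labels
    lv1, lv2 = FACTOR_LEVELS[factor1], FACTOR_LEVELS[factor2]
    out = np.empty((tensor.n_units, len(lv1), len(lv2), len(windows)))
    for i, a in enumerate(lv1):
        for j, b in enumerate(lv2):
            sel = [k for k, l in enumerate(labels)
                   if getattr(l, factor1) == a and getattr(l, factor2) == b
                   and all(getattr(l, d) == v for d, v in fixed.items())]
            if not sel:
                raise ValueError(
                    f"missing factor cell {factor1}={a}, {factor2}={b} "
                    f"in context {fixed}")
            out[:, i, j, :] = rates[:, sel, :].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# demixed axes


@dataclass
class SubspaceResult:
    """Demixed encoder/decoder pairs learned on a training context."""

    factor1: str
    factor2: str
    fixed: dict[str, str]
    windows: list[tuple[float, float]]
    unit_mean: np.ndarray                  # units, removed before projection
    axes: dict[str, np.ndarray]            # marginalization -> units x r (unit norm)
    decoders: dict[str, np.ndarray]        # marginalization -> r x units
    var_explained: dict[str, float]
    train_latents: dict[str, np.ndarray]   # marginalization -> r x n1 x n2 x W


def fit_demixed_axes(tensor: SpikeCountTensor, fixed: dict[str, str],
                     factor1: str, factor2: str,
                     windows: list[tuple[float, float]] | None = None,
                     n_components: dict[str, int] | None = None,
                     ridge: float = 1e-5,
                     trial_subset: np.ndarray | None = None) -> SubspaceResult:
    """Fit demixed axes on the training context.

    For each marginalization phi, finds encoder F (units x r) and decoder
    D (r x units) minimizing ||X_phi - F D X||^2 + ridge penalty, where X
    is the centered condition-mean matrix and X_phi its phi component:
    the ridge-regularized reduced-rank regression at the core of demixed
    PCA.  Default components per marginalization: (levels - 1) for each
    factor, (n1-1)(n2-1) capped at 3 for the interaction.
    """
    windows = windows or sliding_windows()
    M = condition_mean_tensor(tensor, fixed, factor1, factor2, windows,
                              trial_subset=trial_subset)
    n_units = M.shape[0]
    unit_mean = M.mean(axis=(1, 2, 3))
    Mc = M - unit_mean[:, None, None, None]
    parts = marginalize(Mc)
    n1, n2 = M.shape[1], M.shape[2]
    if n_components is None:
        n_components = {"factor1": n1 - 1, "factor2": n2 - 1,
                        "interaction": min((n1 - 1) * (n2 - 1), 3)}
    X = Mc.reshape(n_units, -1)
    total = (X ** 2).sum()
    lam = ridge * total / n_units
    G = X @ X.T + lam * np.eye(n_units)
    axes, decoders, varex, latents = {}, {}, {}, {}
    for key in ("factor1", "factor2", "interaction"):
        r = max(1, min(n_components[key], n_units))
        Xphi = parts[key].reshape(n_units, -1)
        B = Xphi @ X.T @ np.linalg.inv(G)     # full-rank regression map
        U, s, Vt = np.linalg.svd(B @ X, full_matrices=False)
        F = U[:, :r]                           # encoder, unit-norm columns
        D = F.T @ B                            # decoder
        axes[key] = F
        decoders[key] = D
        varex[key] = float((Xphi ** 2).sum() / total) if total > 0 else 0.0
        latents[key] = (D @ X).reshape(r, n1, n2, len(windows))
    varex["residual"] = max(0.0, 1.0 - sum(
        varex[k] for k in ("factor1", "factor2", "interaction")))
    return SubspaceResult(factor1, factor2, fixed, windows, unit_mean,
                          axes, decoders, varex, latents)


def project_heldout(result: SubspaceResult, tensor: SpikeCountTensor,
                    fixed: dict[str, str]) -> dict[str, np.ndarray]:
    """Apply the learned decoders to the held-out context.

    Returns latent condition trajectories per marginalization
    (r x n1 x n2 x windows), centered with the training unit means.
    """
    M = condition_mean_tensor(tensor, fixed, result.factor1, result.factor2,
                              result.windows)
    if M.shape[0] != result.unit_mean.shape[0]:
        raise ValueError("unit count mismatch between training and test data")
    Xc = (M - result.unit_mean[:, None, None, None]).reshape(M.shape[0], -1)
    out = {}
    for key, D in result.decoders.items():
        out[key] = (D @ Xc).reshape(D.shape[0], M.shape[1], M.shape[2],
                                    len(result.windows))
    return out


def _latent_separation_d2(result: SubspaceResult, tensor: SpikeCountTensor,
                          fixed: dict[str, str], key: str,
                          rng: np.random.Generator, n_resamples: int = 20,
                          trial_subset: np.ndarray | None = None
                          ) -> tuple[float, float]:
    """Split-half cross-validated squared level separation in latent space.

    Trials of every condition in the context are halved; level-mean
    latent differences from the two halves are multiplied, so noise-only
    separations average to ~0.  For the interaction marginalization the
    ANOVA interaction components of the two halves are multiplied.
    """
    labels = tensor.trial_labels
    allowed = set(range(len(labels))) if trial_subset is None \
        else set(int(i) for i in trial_subset)
    ctx = [i for i, l in enumerate(labels)
           if i in allowed and all(getattr(l, d) == v for d, v in fixed.items())]
    by_cond: dict[tuple, list[int]] = {}
    for i in ctx:
        l = labels[i]
        by_cond.setdefault((getattr(l, result.factor1),
                            getattr(l, result.factor2)), []).append(i)
    samples = []
    for _ in range(n_resamples):
        halves = ([], [])
        for idx in by_cond.values():
            perm = rng.permutation(idx)
            halves[0].extend(perm[: len(idx) // 2])
            halves[1].extend(perm[len(idx) // 2:])
        lat = []
        for h in halves:
            M = condition_mean_tensor(tensor, fixed, result.factor1,
                                      result.factor2, result.windows,
                                      trial_subset=np.array(sorted(h)))
            Xc = (M - result.unit_mean[:, None, None, None]).reshape(M.shape[0], -1)
            D = result.decoders[key]
            lat.append((D @ Xc).reshape(D.shape[0], M.shape[1], M.shape[2], -1))
        d2 = 0.0
        if key == "interaction":
            p0 = marginalize(lat[0])["interaction"]
            p1 = marginalize(lat[1])["interaction"]
            d2 = float((p0 * p1).sum(axis=(0, 3)).mean())
        else:
            axis = 2 if key == "factor1" else 1
            m0 = lat[0].mean(axis=axis)   # r x levels x W
            m1 = lat[1].mean(axis=axis)
            levels = m0.shape[1]
            pairs = list(itertools.combinations(range(levels), 2))
            for i, j in pairs:
                d2 += float(((m0[:, i] - m0[:, j]) *
                             (m1[:, i] - m1[:, j])).sum(axis=0).mean())
            d2 /= len(pairs)
        samples.append(d2)
    se = float(np.std(samples, ddof=1) / np.sqrt(len(samples))) \
        if len(samples) > 1 else 0.0
    return float(np.mean(samples)), se


def subspace_generalization(tensor: SpikeCountTensor, heldout: str = "person",
                            windows: list[tuple[float, float]] | None = None,
                            n_resamples: int = 20, seed: int = 0
                            ) -> pd.DataFrame:
    """Train demixed axes on one level of ``heldout``, test on the other.

    Returns one row per marginalization with cross-validated squared
    separations in train and test contexts and their ratio
    (``generalization``: ~1 full transfer, ~0 none).  Axes are trained on
    the first level of ``heldout``; for touch type (4 levels) the test
    separation is averaged over the three held-out levels.
    """
    levels = FACTOR_LEVELS[heldout]
    factors = [f for f in ("person", "body_part", "touch_type") if f != heldout]
    if windows is None:
        windows = [tensor.timeline.analysis_window]
    rng = np.random.default_rng(seed)
    # split the training context: axes are fit on half the trials, the
    # training separation is measured on the other half, so train and test
    # separations are equally free of axis-overfitting bias
    by_cond: dict = {}
    for i, l in enumerate(tensor.trial_labels):
        if getattr(l, heldout) == levels[0]:
            by_cond.setdefault((getattr(l, factors[0]), getattr(l, factors[1])),
                               []).append(i)
    fit_idx, eval_idx = [], []
    for idx in by_cond.values():
        perm = rng.permutation(idx)
        fit_idx.extend(perm[: len(idx) // 2])
        eval_idx.extend(perm[len(idx) // 2:])
    fit_idx = np.array(sorted(fit_idx))
    eval_idx = np.array(sorted(eval_idx))
    res = fit_demixed_axes(tensor, {heldout: levels[0]}, factors[0], factors[1],
                           windows=windows, trial_subset=fit_idx)
    rows = []
    for key, name in (("factor1", factors[0]), ("factor2", factors[1]),
                      ("interaction", "interaction")):
        d2_train, se_train = _latent_separation_d2(
            res, tensor, {heldout: levels[0]}, key, rng, n_resamples,
            trial_subset=eval_idx)
        d2_test = float(np.mean([
            _latent_separation_d2(res, tensor, {heldout: lv}, key, rng,
                                  n_resamples)[0]
            for lv in levels[1:]]))
        # ratio undefined unless the training separation is reliably positive
        ratio = d2_test / d2_train if d2_train > max(2 * se_train, 0.0) \
            else np.nan
        rows.append({"marginalization": name, "heldout": heldout,
                     "train_d2": d2_train, "test_d2": d2_test,
                     "generalization": ratio,
                     "var_explained": res.var_explained[key]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# discrimination-axis transfer


def learn_discrimination_axis(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    """Unit-norm direction separating two condition trial ensembles.

    Difference of condition means whitened by the pooled diagonal
    variance — the LDA direction under the shared-diagonal-covariance
    assumption.  Scale-invariant up to the whitening.
    """
    X1 = np.atleast_2d(X1)
    X2 = np.atleast_2d(X2)
    if X1.shape[0] < 2 or X2.shape[0] < 2:
        raise ValueError("both conditions need >= 2 trials")
    d = X1.mean(axis=0) - X2.mean(axis=0)
    var = 0.5 * (X1.var(axis=0) + X2.var(axis=0))
    w = d / np.maximum(var, 1e-12)
    norm = np.linalg.norm(w)
    if norm == 0:
        raise ValueError("conditions are identical: axis undefined")
    return w / norm


def _pair_rates(tensor: SpikeCountTensor, pair: tuple[ConditionLabel, ConditionLabel],
                window: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = snap_window(window, tensor.bin_edges)
    dur = tensor.bin_edges[hi] - tensor.bin_edges[lo]
    rates = tensor.counts[:, :, lo:hi].sum(axis=2) / dur
    return (rates[:, tensor.trials_of(pair[0])].T,
            rates[:, tensor.trials_of(pair[1])].T)


def normalized_generalization(train1: np.ndarray, train2: np.ndarray,
                              test1: np.ndarray, test2: np.ndarray,
                              n_resamples: int = 50, seed: int = 0) -> float:
    """Axis-transfer index: test-pair distance over train-pair distance.

    Per resample, each train condition's trials are split into thirds:
    one third learns the axis, the other two provide independent
    estimates of the projected mean difference whose product estimates
    the squared train distance without overfitting bias.  The test trials
    are split into two halves the same way (the axis never sees them).
    Numerators and denominators are averaged over resamples before the
    ratio is taken.  If test data coincide with train data the index is
    exactly 1; for identical test distributions it concentrates near 0.
    """
    rng = np.random.default_rng(seed)
    same = train1.shape == test1.shape and np.array_equal(train1, test1) \
        and np.array_equal(train2, test2)
    nums, dens, floors = [], [], []
    n1, n2 = train1.shape[0], train2.shape[0]
    for _ in range(n_resamples):
        p1, p2 = rng.permutation(n1), rng.permutation(n2)
        thirds1 = np.array_split(p1, 3)
        thirds2 = np.array_split(p2, 3)
        w = learn_discrimination_axis(train1[thirds1[0]], train2[thirds2[0]])
        da = (train1[thirds1[1]] @ w).mean() - (train2[thirds2[1]] @ w).mean()
        db = (train1[thirds1[2]] @ w).mean() - (train2[thirds2[2]] @ w).mean()
        dens.append(da * db)
        # null scale of da*db: product of two independent mean differences
        v1 = np.var(train1 @ w, ddof=1)
        v2 = np.var(train2 @ w, ddof=1)
        floors.append(v1 / max(len(thirds1[1]), 1) + v2 / max(len(thirds2[1]), 1))
        if same:
            ea = (test1[thirds1[1]] @ w).mean() - (test2[thirds2[1]] @ w).mean()
            eb = (test1[thirds1[2]] @ w).mean() - (test2[thirds2[2]] @ w).mean()
        else:
            q1 = rng.permutation(test1.shape[0])
            q2 = rng.permutation(test2.shape[0])
            h1a, h1b = np.array_split(q1, 2)
            h2a, h2b = np.array_split(q2, 2)
            ea = (test1[h1a] @ w).mean() - (test2[h2a] @ w).mean()
            eb = (test1[h1b] @ w).mean() - (test2[h2b] @ w).mean()
        nums.append(ea * eb)
    den = float(np.mean(dens))
    den_se = float(np.std(dens, ddof=1) / np.sqrt(len(dens))) if len(dens) > 1 \
        else 0.0
    # precondition: the training pair must separate reliably along the axis
    if den <= 0 or (not same and (den < 2 * den_se or den < 2 * np.mean(floors))):
        raise ValueError("train-pair separation not distinguishable from zero; "
                         "index undefined for this pair")
    return float(np.mean(nums) / den)


def axis_transfer_session(tensor: SpikeCountTensor,
                          train_pair: tuple[ConditionLabel, ConditionLabel],
                          test_pair: tuple[ConditionLabel, ConditionLabel],
                          window: tuple[float, float] | None = None,
                          n_resamples: int = 50, seed: int = 0) -> float:
    """Normalized generalization for one session and one pair arrangement."""
    window = window or tensor.timeline.analysis_window
    tr1, tr2 = _pair_rates(tensor, train_pair, window)
    te1, te2 = _pair_rates(tensor, test_pair, window)
    return normalized_generalization(tr1, tr2, te1, te2,
                                     n_resamples=n_resamples, seed=seed)


def _swap(label: ConditionLabel, dim: str, level: str) -> ConditionLabel:
    kw = dict(person=label.person, body_part=label.body_part,
              touch_type=label.touch_type, task=label.task)
    kw[dim] = level
    return ConditionLabel(**kw)


def axis_transfer_suite(tensor: SpikeCountTensor, info_dim: str,
                        across_dim: str, n_resamples: int = 50,
                        seed: int = 0) -> pd.DataFrame:
    """All pair arrangements testing how ``info_dim`` information
    generalizes across ``across_dim`` (one session).

    For every base context, the train pair differs only along
    ``info_dim``; the test pair is the same pair with ``across_dim``
    switched to its other level (touch-type ``across_dim`` uses every
    ordered level change).
    """
    rows = []
    labels = sorted(set(tensor.trial_labels))
    info_levels = FACTOR_LEVELS[info_dim]
    pairs = list(itertools.combinations(info_levels, 2))
    seen = set()
    rng = np.random.default_rng(seed)
    for base in labels:
        for la, lb in pairs:
            if getattr(base, info_dim) != la:
                continue
            c1, c2 = base, _swap(base, info_dim, lb)
            for to_level in FACTOR_LEVELS[across_dim]:
                if to_level == getattr(base, across_dim):
                    continue
                t1, t2 = _swap(c1, across_dim, to_level), _swap(c2, across_dim, to_level)
                key = (c1, c2, t1, t2)
                if key in seen or t1 not in labels or t2 not in labels:
                    continue
                seen.add(key)
                try:
                    val = axis_transfer_session(
                        tensor, (c1, c2), (t1, t2), n_resamples=n_resamples,
                        seed=int(rng.integers(2 ** 31)))
                except ValueError as e:
                    logging.getLogger(__name__).warning(
                        "pair (%s|%s) excluded: %s", c1, c2, e)
                    val = np.nan
                rows.append({"info_dim": info_dim, "across_dim": across_dim,
                             "train_pair": f"{c1.sensory_field}:{c1.touch_type}"
                                           f"|{c2.sensory_field}:{c2.touch_type}",
                             "test_pair": f"{t1.sensory_field}:{t1.touch_type}"
                                          f"|{t2.sensory_field}:{t2.touch_type}",
                             "generalization": val})
    return pd.DataFrame(rows)
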