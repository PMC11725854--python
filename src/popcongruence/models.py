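"""Congruency-model enumeration, fitting, selection, and categorization.

A *congruency model* is a hypothesis about how a neuron's selectivity is
shared across the four sensory fields (Ac, As, Oc, Os).  Each field is
either unresponsive or assigned to a class; fields in the same class
share one response profile.  Two modes exist:

``binary``
    One shared response scalar: every responsive field carries the same
    0/1 weighting coefficient.  With 4 fields there are 2**4 = 16 models,
    including the fully unresponsive one.  Used for the 4-condition task
    (BSMT), where only rubs are delivered.

``sp_sharing``
    Responsive fields are partitioned into classes; each class carries
    its own *selectivity pattern* (SP) — a 4-vector of responses to the
    touch types pinch, press, rub, tap.  Counting partitions of every
    nonempty subset of the 4 fields gives
    sum_{k=1..4} C(4,k) * Bell(k) = 51 models (the fully unresponsive
    assignment is excluded).  Used for the 16-condition task (MSMT).

Models are kept in canonical form: class ids are renumbered by first
appearance in field order Ac, As, Oc, Os, so two assignments are equal
iff they induce the same partition of the responsive fields.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .data_model import FIELDS, TOUCH_TYPES, ConditionLabel

#: numerical floor for per-trial residual variance in the BIC (Hz^2)
RSS_FLOOR = 1e-12
#: BIC ties within this are broken toward fewer parameters
BIC_TIE_TOL = 1e-9


def canonicalize(assignment: tuple[int, ...]) -> tuple[int, ...]:
    """Renumber class ids by first appearance; 0 stays 'unresponsive'."""
    mapping: dict[int, int] = {}
    out = []
    for a in assignment:
        if a == 0:
            out.append(0)
        else:
            if a not in mapping:
                mapping[a] = len(mapping) + 1
            out.append(mapping[a])
    return tuple(out)


@dataclass(frozen=True)
class CongruencyModel:
    """Canonical assignment of sensory fields to shared-response classes.

    ``assignment[i]`` is 0 if field ``FIELDS[i]`` is unresponsive, else
    the class id (1-based, numbered by first appearance).
    """

    assignment: tuple[int, ...]
    mode: str = "sp_sharing"  # or "binary"

    def __post_init__(self):
        if self.mode not in ("binary", "sp_sharing"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if canonicalize(self.assignment) != tuple(self.assignment):
            raise ValueError(f"assignment {self.assignment} is not canonical")
        if self.mode == "binary" and self.n_classes > 1:
            raise ValueError("binary models have a single shared class")

    @property
    def n_fields(self) -> int:
        return len(self.assignment)

    @property
    def n_classes(self) -> int:
        return max(self.assignment, default=0)

    @property
    def responsive_fields(self) -> tuple[int, ...]:
        return tuple(i for i, a in enumerate(self.assignment) if a > 0)

    @property
    def model_id(self) -> str:
        tag = "b" if self.mode == "binary" else "s"
        return tag + "".join(str(a) for a in self.assignment)

    def n_params(self, mode_touch: bool | None = None) -> int:
        """Number of regression coefficients.

        One per class in binary mode; one per (class, touch type) in
        sp_sharing mode.
        """
        per_class = 1 if self.mode == "binary" else len(TOUCH_TYPES)
        return self.n_classes * per_class

    def __str__(self) -> str:  # e.g. "{Ac,Oc}=1 {As,Os}=2"
        if self.n_classes == 0:
            return "unresponsive"
        parts = []
        for c in range(1, self.n_classes + 1):
            names = [FIELDS[i] for i, a in enumerate(self.assignment) if a == c]
            parts.append("{" + ",".join(names) + "}=" + str(c))
        return " ".join(parts)


def enumerate_models(n_fields: int = 4, mode: str = "sp_sharing"
                     ) -> list[CongruencyModel]:
    """Exhaustive, duplicate-free, canonical model list.

    binary mode includes the all-unresponsive model (2**n models);
    sp_sharing excludes it (51 models for 4 fields).
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    seen: dict[tuple[int, ...], None] = {}
    max_class = 1 if mode == "binary" else n_fields
    for labeling in itertools.product(range(max_class + 1), repeat=n_fields):
        canon = canonicalize(labeling)
        if mode == "sp_sharing" and all(a == 0 for a in canon):
            continue
        seen.setdefault(canon, None)
    return [CongruencyModel(a, mode) for a in sorted(seen)]


# ---------------------------------------------------------------------------
# categorization


def categorize(model: CongruencyModel, extended: bool | None = None) -> str:
    """Map a canonical model to a structural neuron category.

    Binary (4-way, following the basic-task taxonomy): ``invariant``
    (one shared coefficient across all four fields), ``body_part_specific``
    (coefficients match within cheek and within shoulder but not across —
    the mirror-like pattern), ``person_specific`` (match within actual and
    within observed), else ``idiosyncratic``.

    sp_sharing (8-way structural taxonomy): the four above generalize to
    class assignments (unresponsive counts as matching unresponsive), plus
    ``single_field``, ``three_field_one_class``, ``two_class_other``, and
    ``non_responsive``.
    """
    if extended is None:
        extended = model.mode == "sp_sharing"
    a = model.assignment
    if len(a) != 4:
        raise ValueError("categorization is defined for the 4-field design")
    ac, as_, oc, os_ = a
    n_resp = len(model.responsive_fields)
    all_same_responsive = n_resp == 4 and model.n_classes == 1
    body_part_match = (ac == oc) and (as_ == os_)
    person_match = (ac == as_) and (oc == os_)

    if not extended:
        if n_resp == 0:
            return "idiosyncratic"  # "other patterns"; no modulation anywhere
        if all_same_responsive:
            return "invariant"
        if body_part_match:
            return "body_part_specific"
        if person_match:
            return "person_specific"
        return "idiosyncratic"

    if n_resp == 0:
        return "non_responsive"
    if all_same_responsive:
        return "invariant"
    if body_part_match:
        return "body_part_specific"
    if person_match:
        return "person_specific"
    if n_resp == 1:
        return "single_field"
    if n_resp == 3 and model.n_classes == 1:
        return "three_field_one_class"
    if model.n_classes == 2:
        return "two_class_other"
    return "idiosyncratic"


BSMT_CATEGORIES = ("invariant", "body_part_specific", "person_specific",
                   "idiosyncratic")
MSMT_CATEGORIES = ("invariant", "body_part_specific", "person_specific",
                   "single_field", "three_field_one_class", "two_class_other",
                   "idiosyncratic", "non_responsive")


# ---------------------------------------------------------------------------
# design matrices and fitting


def design_matrix(model: CongruencyModel, labels: list[ConditionLabel]
                  ) -> tuple[np.ndarray, list[str]]:
    """Trial-indicator design for a model, with column meanings.

    Responses are modeled relative to the pre-stimulus baseline, so no
    intercept column is used: a trial in an unresponsive field predicts 0
    (the per-field weighting collapses to the baseline scalar).  binary
    mode: one pooled column per class; sp_sharing: one column per
    (class, touch type).  Every enumerated model's matrix then has full
    column rank on the balanced factorial design.
    """
    field_idx = {f: i for i, f in enumerate(FIELDS)}
    fields = np.array([field_idx[l.sensory_field] for l in labels])
    classes = np.array([model.assignment[f] for f in fields])
    cols, names = [], []
    for c in range(1, model.n_classes + 1):
        members = "{" + ",".join(
            FIELDS[i] for i, a in enumerate(model.assignment) if a == c) + "}"
        if model.mode == "binary":
            cols.append((classes == c).astype(float))
            names.append(members)
        else:
            touch = np.array([TOUCH_TYPES.index(l.touch_type) for l in labels])
            for t, tname in enumerate(TOUCH_TYPES):
                cols.append(((classes == c) & (touch == t)).astype(float))
                names.append(f"{members}:{tname}")
    X = np.column_stack(cols) if cols else np.zeros((len(labels), 0))
    return X, names


def _stratified_folds(labels: list[ConditionLabel], n_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    """Condition-stratified fold assignment over trials."""
    by_cond: dict[ConditionLabel, list[int]] = {}
    for i, l in enumerate(labels):
        by_cond.setdefault(l, []).append(i)
    fold_of = np.empty(len(labels), dtype=int)
    for idx in by_cond.values():
        idx = np.array(idx)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % n_folds
    return [np.flatnonzero(fold_of == f) for f in range(n_folds)]


@dataclass
class ModelFitResult:
    """Per-neuron fit of every candidate congruency model."""

    models: list[CongruencyModel]
    bic: np.ndarray            # per model
    cvr2: np.ndarray           # per model
    coefs: list[np.ndarray]    # per model, per design column
    best_by_bic: str | None
    best_by_cvr2: str | None
    zero_variance: bool = False

    def best_model(self, criterion: str = "bic") -> CongruencyModel | None:
        mid = self.best_by_bic if criterion == "bic" else self.best_by_cvr2
        if mid is None:
            return None
        return next(m for m in self.models if m.model_id == mid)


def _pick_best(scores: np.ndarray, n_params: np.ndarray, minimize: bool
               ) -> int:
    """Index of the best score, ties broken toward fewer parameters."""
    s = scores if minimize else -scores
    best = np.min(s)
    tied = np.flatnonzero(s <= best + BIC_TIE_TOL)
    return int(tied[np.argmin(n_params[tied])])


def fit_models_population(Y: np.ndarray, labels: list[ConditionLabel],
                          models: list[CongruencyModel],
                          cv_folds: int = 10, seed: int = 0
                          ) -> tuple[np.ndarray, np.ndarray, list[list[np.ndarray]]]:
    """Fit every model to every unit at once (shared designs).

    Y : units x trials array of baseline-subtracted rates (Hz).
    Returns (bic, cvr2) arrays of shape units x models and per-model
    coefficient lists.  BIC = n*ln(RSS/n) + k*ln(n) on the OLS residual;
    cvR^2 = 1 - SS_res/SS_tot on held-out folds of a condition-stratified
    K-fold split (SS_tot about the training-fold mean), folds seeded and
    shared across models so scores are comparable.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    n_units, n = Y.shape
    rng = np.random.default_rng(seed)
    folds = _stratified_folds(labels, cv_folds, rng)
    bic = np.empty((n_units, len(models)))
    cvr2 = np.empty((n_units, len(models)))
    all_coefs: list[list[np.ndarray]] = [[] for _ in range(n_units)]
    log_n = np.log(n)
    for j, model in enumerate(models):
        X, _ = design_matrix(model, labels)
        k = X.shape[1]
        if k:
            beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
            resid = Y.T - X @ beta
        else:
            beta = np.zeros((0, n_units))
            resid = Y.T
        rss = np.maximum((resid ** 2).sum(axis=0), n * RSS_FLOOR)
        bic[:, j] = n * np.log(rss / n) + k * log_n
        for u in range(n_units):
            all_coefs[u].append(beta[:, u].copy())
        # cross-validated R^2
        ss_res = np.zeros(n_units)
        ss_tot = np.zeros(n_units)
        for test in folds:
            train = np.setdiff1d(np.arange(n), test)
            if k:
                b, *_ = np.linalg.lstsq(X[train], Y[:, train].T, rcond=None)
                pred = X[test] @ b
            else:
                pred = np.zeros((len(test), n_units))
            ss_res += ((Y[:, test].T - pred) ** 2).sum(axis=0)
            ybar = Y[:, train].mean(axis=1)
            ss_tot += ((Y[:, test].T - ybar) ** 2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            cvr2[:, j] = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, -np.inf)
    return bic, cvr2, all_coefs


def fit_and_select(rates: np.ndarray, labels: list[ConditionLabel],
                   models: list[CongruencyModel], cv_folds: int = 10,
                   seed: int = 0) -> ModelFitResult:
    """Fit all candidate models to one neuron and select the best.

    ``rates`` are per-trial baseline-subtracted rates (Hz).  Best by BIC
    minimizes BIC; best by cvR^2 maximizes it; exact ties break toward
    fewer parameters (then canonical order).  A zero-variance neuron is
    flagged and assigned no best model (non-responsive baseline).
    """
    rates = np.asarray(rates, dtype=float)
    if np.ptp(rates) == 0 and abs(rates[0]) < 1e-12:
        nan = np.full(len(models), np.nan)
        return ModelFitResult(models, nan, nan, [np.array([])] * len(models),
                              None, None, zero_variance=True)
    bic, cvr2, coefs = fit_models_population(
        rates[None, :], labels, models, cv_folds=cv_folds, seed=seed)
    n_params = np.array([m.n_params() for m in models])
    i_bic = _pick_best(bic[0], n_params, minimize=True)
    i_cv = _pick_best(cvr2[0], n_params, minimize=False)
    return ModelFitResult(models, bic[0], cvr2[0], coefs[0],
                          models[i_bic].model_id, models[i_cv].model_id)


def select_best_population(Y: np.ndarray, labels: list[ConditionLabel],
                           models: list[CongruencyModel], cv_folds: int = 10,
                           seed: int = 0) -> "pd.DataFrame":
    """Best model per unit by both criteria (vectorized over units)."""
    import pandas as pd

    bic, cvr2, _ = fit_models_population(Y, labels, models,
                                         cv_folds=cv_folds, seed=seed)
    n_params = np.array([m.n_params() for m in models])
    rows = []
    for u in range(bic.shape[0]):
        i_b = _pick_best(bic[u], n_params, minimize=True)
        i_c = _pick_best(cvr2[u], n_params, minimize=False)
        rows.append({
            "unit": u,
            "best_by_bic": models[i_b].model_id,
            "best_by_cvr2": models[i_c].model_id,
            "bic": bic[u, i_b],
            "cvr2": cvr2[u, i_c],
            "category_bic": categorize(models[i_b]),
            "category_cvr2": categorize(models[i_c]),
        })
    return pd.DataFrame(rows)


def population_model_histogram(best: "pd.DataFrame") -> dict[str, "pd.DataFrame"]:
    """Percentages of units per best model and per category, per criterion.

    ``best`` is the output of :func:`select_best_population` (optionally
    concatenated across sessions).
    """
    import pandas as pd

    out = {}
    n = len(best)
    for crit in ("bic", "cvr2"):
        out[f"model_{crit}"] = (
            best[f"best_by_{crit}"].value_counts().mul(100.0 / n)
            .rename("percent").rename_axis("model_id").reset_index()
        )
        out[f"category_{crit}"] = (
            best[f"category_{crit}"].value_counts().mul(100.0 / n)
            .rename("percent").rename_axis("category").reset_index()
        )
    return out
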