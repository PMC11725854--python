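"""Synthetic spike-count generator with known ground truth.

Emulates the two touch tasks: the basic task (BSMT; 4 conditions = person
x body part, rubs only; 6 sessions of ~126 units) and the
multidimensional task (MSMT; 16 conditions = person x body part x touch
type; 8 sessions of ~119 units), each with 10 trials per condition, 3 s
of stimulation and a 1 s pre-stimulus baseline.

Two generative regimes are provided:

* per-neuron congruency models (:func:`generate_population`): each unit is
  drawn from a mixture over candidate congruency models; responsive
  sensory fields add a selectivity-pattern increment on top of a Poisson
  baseline.  The ground-truth model of every unit is returned so that
  model-selection recovery can be scored.
* population-level compositional structure
  (:func:`generate_compositional_population`): unit rates are a linear
  composition of low-rank body-part and touch-type loadings, an optional
  context-specific interaction term, and a person term — the regime the
  subspace-generalization analyses target.

Units respond with a step at a ~60 ms sensory latency, sustained through
0.5 s after stimulation offset so that the mean rate over the standard
analysis window equals baseline + increment exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    FIELDS,
    TOUCH_TYPES,
    ConditionLabel,
    SpikeCountTensor,
    TrialTimeline,
    condition_labels,
    make_bin_edges,
)
from .io import Experiment
from .models import CongruencyModel, enumerate_models

LATENCY = 0.06  # s, sensory response latency


# ---------------------------------------------------------------------------
# single-neuron generation


@dataclass
class NeuronGenSpec:
    """Generative description of one unit.

    sp_per_class maps class id -> selectivity pattern: a 4-vector of Hz
    increments per touch type (pinch, press, rub, tap) in sp_sharing
    mode, or a scalar increment in binary mode.
    """

    baseline: float
    model: CongruencyModel
    sp_per_class: dict[int, np.ndarray | float]
    noise: str = "poisson"      # "poisson", "gaussian", or "none"
    noise_sigma: float = 1.0    # Hz, across-trial rate SD in gaussian mode

    def __post_init__(self):
        if self.baseline < 0:
            raise ValueError("baseline must be >= 0")
        for c in range(1, self.model.n_classes + 1):
            if c not in self.sp_per_class:
                raise ValueError(f"model class {c} lacks a selectivity pattern")

    def expected_rate(self, label: ConditionLabel) -> float:
        """Expected analysis-window rate (Hz) for one condition."""
        cls = self.model.assignment[FIELDS.index(label.sensory_field)]
        if cls == 0:
            return self.baseline
        sp = self.sp_per_class[cls]
        inc = float(sp) if np.isscalar(sp) else float(
            np.asarray(sp)[TOUCH_TYPES.index(label.touch_type)])
        rate = self.baseline + inc
        if rate < 0:
            raise ValueError(
                f"negative expected rate {rate:.3g} Hz for {label}")
        return rate


def _active_mask(bin_edges: np.ndarray, timeline: TrialTimeline) -> np.ndarray:
    """Bins during which the response increment applies.

    The response steps on at the sensory latency and is sustained through
    0.5 s after stimulation offset (plus latency), so it covers the whole
    analysis window [0.5, stim_duration + 0.5].
    """
    centers = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    return (centers >= LATENCY) & (centers < timeline.stim_duration + 0.5 + LATENCY)


def _deterministic_counts(lam: np.ndarray) -> np.ndarray:
    """Spread expected counts over bins by cumulative rounding (no noise)."""
    cum = np.cumsum(lam, axis=-1)
    r = np.round(cum).astype(np.int64)
    return np.diff(np.concatenate([np.zeros(r.shape[:-1] + (1,), np.int64), r],
                                  axis=-1), axis=-1)


def generate_neuron(spec: NeuronGenSpec, labels: list[ConditionLabel],
                    timeline: TrialTimeline, seed: int | np.random.Generator = 0
                    ) -> np.ndarray:
    """Simulate one unit: trials x bins spike counts."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bin_edges = make_bin_edges(timeline.coverage)
    bw = bin_edges[1] - bin_edges[0]
    active = _active_mask(bin_edges, timeline)
    rates = np.array([spec.expected_rate(l) for l in labels])  # trials
    inc = rates - spec.baseline
    lam_rate = spec.baseline + inc[:, None] * active[None, :]  # trials x bins
    if spec.noise == "gaussian":
        lam_rate = lam_rate + rng.normal(0.0, spec.noise_sigma, size=(len(labels), 1))
        lam_rate = np.clip(lam_rate, 0.0, None)
    lam = lam_rate * bw
    if spec.noise == "poisson":
        return rng.poisson(lam)
    return _deterministic_counts(lam)


# ---------------------------------------------------------------------------
# population generation


@dataclass
class PopulationGenSpec:
    """Population-level generative settings.

    model_mixture maps model_id -> probability; any unspecified mass is
    spread uniformly over the remaining candidate models of the task.
    SP increments are drawn uniformly from sp_range (Hz) per touch type
    and class; baselines uniformly from baseline_range (Hz).  These
    magnitudes are plausibility choices, not measured values.
    """

    n_units: int = 119
    n_sessions: int = 8
    trials_per_condition: int = 10
    model_mixture: dict[str, float] | None = None
    baseline_range: tuple[float, float] = (1.0, 10.0)
    sp_range: tuple[float, float] = (2.0, 15.0)
    noise: str = "poisson"
    noise_sigma: float = 1.0
    stable_population: bool = False   # reuse the same units every session
    snr_range: tuple[float, float] = (0.2, 3.0)
    seed: int = 0
    timeline: TrialTimeline = field(default_factory=TrialTimeline)

    def __post_init__(self):
        if self.trials_per_condition < 2:
            raise ValueError("trials_per_condition must be >= 2 (split-half)")


def default_mixture(task: str) -> dict[str, float]:
    """Default model mixture: mostly idiosyncratic/complex units with a
    minority of body-part-specific (mirror-like) congruent units, echoing
    the heterogeneity of the recorded populations (12% mirror-like in the
    basic task, 3% in the multidimensional task) without asserting their
    exact real-data values."""
    if task == "BSMT":
        return {
            "b1111": 0.10,            # invariant
            "b1010": 0.06, "b0101": 0.06,   # body-part specific (mirror-like)
            "b1100": 0.05, "b0011": 0.05,   # person specific
            "b1000": 0.10, "b0100": 0.10, "b0010": 0.10, "b0001": 0.10,
            "b0000": 0.08,            # unresponsive
        }
    return {
        "s1212": 0.03,                # body-part specific (mirror-like)
        "s1111": 0.05,                # invariant
        "s1122": 0.04,                # person specific
        "s1000": 0.12, "s0100": 0.12, "s0010": 0.12, "s0001": 0.12,
    }


def _resolve_mixture(mixture: dict[str, float] | None, task: str
                     ) -> tuple[list[CongruencyModel], np.ndarray]:
    mode = "binary" if task == "BSMT" else "sp_sharing"
    catalog = enumerate_models(4, mode)
    ids = [m.model_id for m in catalog]
    if mixture is None:
        mixture = default_mixture(task)
    unknown = set(mixture) - set(ids)
    if unknown:
        raise ValueError(f"mixture references unknown model ids: {sorted(unknown)}")
    probs = np.zeros(len(catalog))
    for mid, p in mixture.items():
        probs[ids.index(mid)] = p
    total = probs.sum()
    if total > 1 + 1e-9:
        raise ValueError(f"mixture probabilities sum to {total:.3f} > 1")
    rest = np.flatnonzero(probs == 0)
    if rest.size and total < 1:
        probs[rest] = (1 - total) / rest.size
    probs /= probs.sum()
    return catalog, probs


def _session_trials(task: str, trials_per_condition: int,
                    rng: np.random.Generator) -> list[ConditionLabel]:
    labels = [c for c in condition_labels(task) for _ in range(trials_per_condition)]
    order = rng.permutation(len(labels))
    return [labels[i] for i in order]


def draw_neuron_spec(model: CongruencyModel, spec: PopulationGenSpec,
                     rng: np.random.Generator) -> NeuronGenSpec:
    baseline = rng.uniform(*spec.baseline_range)
    sp_per_class: dict[int, np.ndarray | float] = {}
    for c in range(1, model.n_classes + 1):
        if model.mode == "binary":
            sp_per_class[c] = float(rng.uniform(*spec.sp_range))
        else:
            sp_per_class[c] = rng.uniform(*spec.sp_range, size=len(TOUCH_TYPES))
    return NeuronGenSpec(baseline, model, sp_per_class,
                         noise=spec.noise, noise_sigma=spec.noise_sigma)


def _simulate_session(specs: list[NeuronGenSpec], labels: list[ConditionLabel],
                      timeline: TrialTimeline, session_id: int,
                      snr: np.ndarray, rng: np.random.Generator
                      ) -> SpikeCountTensor:
    bin_edges = make_bin_edges(timeline.coverage)
    bw = bin_edges[1] - bin_edges[0]
    active = _active_mask(bin_edges, timeline)
    n_units, n_trials, n_bins = len(specs), len(labels), len(bin_edges) - 1
    base = np.array([s.baseline for s in specs])
    inc = np.array([[s.expected_rate(l) - s.baseline for l in labels]
                    for s in specs])                      # units x trials
    lam_rate = base[:, None, None] + inc[:, :, None] * active[None, None, :]
    if specs[0].noise == "gaussian":
        jit = rng.normal(0.0, np.array([s.noise_sigma for s in specs])[:, None, None],
                         size=(n_units, n_trials, 1))
        lam_rate = np.clip(lam_rate + jit, 0.0, None)
    lam = lam_rate * bw
    if specs[0].noise == "poisson":
        counts = rng.poisson(lam)
    else:
        counts = _deterministic_counts(lam)
    total_dur = bin_edges[-1] - bin_edges[0]
    meta = pd.DataFrame({
        "mean_rate": counts.sum(axis=(1, 2)) / (n_trials * total_dur),
        "snr": snr,
    })
    return SpikeCountTensor(counts=counts, bin_edges=bin_edges,
                            trial_labels=labels, session_id=session_id,
                            unit_meta=meta, timeline=timeline)


def generate_population(spec: PopulationGenSpec, task: str = "MSMT"
                        ) -> Experiment:
    """Simulate a multi-session experiment from a congruency-model mixture.

    Returns an :class:`Experiment` whose ``truth`` table records, per
    (session, unit, class), the generative model id, baseline, and SP.
    Fixing ``spec.seed`` fixes every downstream analysis bit-for-bit.
    """
    catalog, probs = _resolve_mixture(spec.model_mixture, task)
    root = np.random.default_rng(spec.seed)
    truth_rows = []
    sessions = []
    stable_specs: list[NeuronGenSpec] | None = None
    for sid in range(spec.n_sessions):
        rng = np.random.default_rng(root.integers(2 ** 31))
        if spec.stable_population and stable_specs is not None:
            specs = stable_specs
        else:
            draws = rng.choice(len(catalog), size=spec.n_units, p=probs)
            specs = [draw_neuron_spec(catalog[i], spec, rng) for i in draws]
            if spec.stable_population:
                stable_specs = specs
        labels = _session_trials(task, spec.trials_per_condition, rng)
        snr = rng.uniform(*spec.snr_range, size=spec.n_units)
        sessions.append(_simulate_session(specs, labels, spec.timeline, sid, snr, rng))
        for u, ns in enumerate(specs):
            if ns.model.n_classes == 0:
                truth_rows.append(dict(unit=u, session=sid,
                                       model_id=ns.model.model_id,
                                       baseline_hz=ns.baseline, sp_class=0,
                                       sp_pinch=0.0, sp_press=0.0,
                                       sp_rub=0.0, sp_tap=0.0))
                continue
            for c in range(1, ns.model.n_classes + 1):
                sp = ns.sp_per_class[c]
                if ns.model.mode == "binary":
                    sp4 = [0.0, 0.0, float(sp), 0.0]  # rub-only increment
                else:
                    sp4 = [float(v) for v in np.asarray(sp)]
                truth_rows.append(dict(unit=u, session=sid,
                                       model_id=ns.model.model_id,
                                       baseline_hz=ns.baseline, sp_class=c,
                                       sp_pinch=sp4[0], sp_press=sp4[1],
                                       sp_rub=sp4[2], sp_tap=sp4[3]))
    truth = pd.DataFrame(truth_rows)
    return Experiment(sessions=sessions, task=task, truth=truth)


# ---------------------------------------------------------------------------
# compositional populations


@dataclass
class CompositionalSpec:
    """Low-rank compositional population structure (16-condition task).

    Mean rate of unit u in condition (person p, body part b, touch t):

        mu_u = baseline_u + g_p * (W_body[u, b] + W_touch[u, t])
               + kappa * W_int[p][u, (b, t)] + person_gain * w_person[u] * [p = observed]

    with g_actual = 1 and g_observed = observed_scale.  The interaction
    loadings W_int are drawn independently per person context, so the
    b x t interaction is context-specific and does not transfer across
    contexts by construction; the additive body/touch loadings are shared
    and do.  observed_scale = 0 yields a person-specific population with
    no factor signal in the observed context; person_gain = 0 and
    observed_scale = 1 yield populations exchangeable across persons.
    """

    n_units: int = 119
    n_sessions: int = 4
    trials_per_condition: int = 10
    baseline: float = 8.0
    loading_scale: float = 2.0      # Hz, SD of W_body / W_touch entries
    rank_body: int = 1
    rank_touch: int = 3
    kappa: float = 0.0
    observed_scale: float = 1.0
    person_gain: float = 0.0
    noise: str = "poisson"
    noise_sigma: float = 1.0
    seed: int = 0
    timeline: TrialTimeline = field(default_factory=TrialTimeline)


def _low_rank_loadings(n_units: int, n_levels: int, rank: int, scale: float,
                       rng: np.random.Generator) -> np.ndarray:
    """units x levels loading matrix of the given rank, column-centered."""
    U = rng.normal(0.0, 1.0, size=(n_units, rank))
    V = rng.normal(0.0, 1.0, size=(rank, n_levels))
    W = U @ V
    W -= W.mean(axis=1, keepdims=True)      # factor effects sum to zero
    W *= scale / max(W.std(), 1e-12)
    return W


def generate_compositional_population(spec: CompositionalSpec
                                      ) -> tuple[Experiment, dict]:
    """Simulate a compositional population; returns (experiment, latents).

    ``latents`` holds the loading matrices and the units x 16 matrix of
    expected condition rates per session, in canonical condition order.
    """
    root = np.random.default_rng(spec.seed)
    labels16 = condition_labels("MSMT")
    sessions, latents = [], {"sessions": []}
    for sid in range(spec.n_sessions):
        rng = np.random.default_rng(root.integers(2 ** 31))
        W_body = _low_rank_loadings(spec.n_units, 2, spec.rank_body,
                                    spec.loading_scale, rng)
        W_touch = _low_rank_loadings(spec.n_units, 4, spec.rank_touch,
                                     spec.loading_scale, rng)
        W_int = {}
        for p in ("actual", "observed"):
            W = _low_rank_loadings(spec.n_units, 8, min(3, spec.n_units),
                                   spec.loading_scale, rng)
            # double-center over the body x touch grid so the term is a pure
            # interaction with zero factor marginals
            G = W.reshape(spec.n_units, 2, 4)
            G = (G - G.mean(axis=1, keepdims=True) - G.mean(axis=2, keepdims=True)
                 + G.mean(axis=(1, 2), keepdims=True))
            W_int[p] = G.reshape(spec.n_units, 8)
        w_person = rng.normal(0.0, 1.0, size=spec.n_units)
        mu = np.empty((spec.n_units, len(labels16)))
        for j, lab in enumerate(labels16):
            b = ("cheek", "shoulder").index(lab.body_part)
            t = TOUCH_TYPES.index(lab.touch_type)
            g = 1.0 if lab.person == "actual" else spec.observed_scale
            m = (spec.baseline + g * (W_body[:, b] + W_touch[:, t])
                 + spec.kappa * W_int[lab.person][:, b * 4 + t])
            if lab.person == "observed":
                m = m + spec.person_gain * w_person
            mu[:, j] = m
        mu = np.clip(mu, 0.05, None)
        trial_labels = _session_trials("MSMT", spec.trials_per_condition, rng)
        cond_idx = {lab: j for j, lab in enumerate(labels16)}
        bin_edges = make_bin_edges(spec.timeline.coverage)
        bw = bin_edges[1] - bin_edges[0]
        active = _active_mask(bin_edges, spec.timeline)
        inc = mu[:, [cond_idx[l] for l in trial_labels]] - spec.baseline
        lam_rate = spec.baseline + inc[:, :, None] * active[None, None, :]
        if spec.noise == "gaussian":
            jit = rng.normal(0.0, spec.noise_sigma,
                             size=(spec.n_units, len(trial_labels), 1))
            lam_rate = np.clip(lam_rate + jit, 0.0, None)
        lam = lam_rate * bw
        counts = rng.poisson(lam) if spec.noise == "poisson" else \
            _deterministic_counts(lam)
        total_dur = bin_edges[-1] - bin_edges[0]
        meta = pd.DataFrame({
            "mean_rate": counts.sum(axis=(1, 2)) / (len(trial_labels) * total_dur),
            "snr": rng.uniform(0.5, 3.0, size=spec.n_units),
        })
        sessions.append(SpikeCountTensor(
            counts=counts, bin_edges=bin_edges, trial_labels=trial_labels,
            session_id=sid, unit_meta=meta, timeline=spec.timeline))
        latents["sessions"].append(dict(W_body=W_body, W_touch=W_touch,
                                        W_int=W_int, w_person=w_person,
                                        expected_rates=mu))
    return Experiment(sessions=sessions, task="MSMT"), latents


def census_unit_meta(n_units: int, n_passing: int,
                     seed: int | np.random.Generator = 0,
                     min_rate: float = 0.5, min_snr: float = 0.5
                     ) -> pd.DataFrame:
    """Unit metadata with exactly ``n_passing`` units passing selection.

    Synthetic stand-in for a recorded-unit census (e.g. 805 recorded /
    756 selected in the basic task): passing units get rates and SNRs
    above both thresholds, the remainder fail at least one criterion.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_passing > n_units:
        raise ValueError("n_passing cannot exceed n_units")
    mean_rate = rng.uniform(min_rate + 0.5, 20.0, size=n_units)
    snr = rng.uniform(min_snr + 0.1, 3.0, size=n_units)
    fail = rng.permutation(n_units)[: n_units - n_passing]
    for i in fail:
        if rng.random() < 0.5:
            mean_rate[i] = rng.uniform(0.0, min_rate * 0.9)
        else:
            snr[i] = rng.uniform(0.0, min_snr * 0.9)
    return pd.DataFrame({"mean_rate": mean_rate, "snr": snr})
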