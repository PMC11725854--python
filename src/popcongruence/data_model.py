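"""Core data containers for trial-aligned spike-count recordings.

The experimental design is factorial: touch is delivered to a *person*
(actual touch to the participant, or observed touch to another person),
on a *body part* (cheek or shoulder), with a *touch type* (pinch, press,
rub, tap).  The basic task (BSMT) uses rubs only (2 x 2 = 4 conditions);
the multidimensional task (MSMT) crosses all three factors (16 conditions).
The (person, body part) pair is called a *sensory field* (or format):
Ac, As, Oc, Os.

Spike counts are stored as a dense ``units x trials x bins`` tensor of
nonnegative integers at 10 ms resolution, aligned to stimulus onset
(time 0).  Bins are half-open ``[left, right)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PERSONS = ("actual", "observed")
BODY_PARTS = ("cheek", "shoulder")
TOUCH_TYPES = ("pinch", "press", "rub", "tap")
TASKS = ("BSMT", "MSMT")

#: sensory field (format) short codes in canonical order
FIELDS = ("Ac", "As", "Oc", "Os")

_FIELD_OF = {
    ("actual", "cheek"): "Ac",
    ("actual", "shoulder"): "As",
    ("observed", "cheek"): "Oc",
    ("observed", "shoulder"): "Os",
}

BIN_WIDTH = 0.01  # s

DEFAULT_COVERAGE = (-1.5, 4.0)  # s, fits every published analysis window


class ValidationError(ValueError):
    """Structured validation failure naming the offending trial/unit/row."""


@dataclass(frozen=True, order=True)
class ConditionLabel:
    """One cell of the factorial design."""

    person: str
    body_part: str
    touch_type: str
    task: str = "MSMT"

    def __post_init__(self):
        if self.person not in PERSONS:
            raise ValidationError(f"unknown person {self.person!r}")
        if self.body_part not in BODY_PARTS:
            raise ValidationError(f"unknown body_part {self.body_part!r}")
        if self.touch_type not in TOUCH_TYPES:
            raise ValidationError(f"unknown touch_type {self.touch_type!r}")
        if self.task not in TASKS:
            raise ValidationError(f"unknown task {self.task!r}")
        if self.task == "BSMT" and self.touch_type != "rub":
            raise ValidationError(
                f"BSMT uses rub only, got touch_type {self.touch_type!r}"
            )

    @property
    def sensory_field(self) -> str:
        """The (person, body part) context: one of Ac, As, Oc, Os."""
        return _FIELD_OF[(self.person, self.body_part)]


def condition_labels(task: str) -> list[ConditionLabel]:
    """All labels of a task, in canonical order.

    Canonical order is person-major (actual before observed), then body
    part (cheek before shoulder), then touch type alphabetically.  All
    matrix condition axes in this package follow this order.
    """
    if task == "BSMT":
        touches = ("rub",)
    elif task == "MSMT":
        touches = TOUCH_TYPES
    else:
        raise ValidationError(f"unknown task {task!r}")
    return [
        ConditionLabel(p, b, t, task)
        for p, b, t in itertools.product(PERSONS, BODY_PARTS, touches)
    ]


@dataclass(frozen=True)
class TrialTimeline:
    """Within-trial timing, in seconds relative to stimulus onset.

    The analysis window starts 0.5 s after stimulus onset and ends 0.5 s
    after stimulation ends; the baseline is the 1 s before onset.
    """

    stim_duration: float = 3.0
    baseline_window: tuple[float, float] = (-1.0, 0.0)
    coverage: tuple[float, float] = DEFAULT_COVERAGE

    @property
    def analysis_window(self) -> tuple[float, float]:
        return (0.5, self.stim_duration + 0.5)

    def to_dict(self) -> dict:
        return {
            "stim_duration": self.stim_duration,
            "baseline_window": list(self.baseline_window),
            "coverage": list(self.coverage),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrialTimeline":
        return cls(
            stim_duration=float(d.get("stim_duration", 3.0)),
            baseline_window=tuple(d.get("baseline_window", (-1.0, 0.0))),
            coverage=tuple(d.get("coverage", DEFAULT_COVERAGE)),
        )


def make_bin_edges(coverage: tuple[float, float] = DEFAULT_COVERAGE,
                   bin_width: float = BIN_WIDTH) -> np.ndarray:
    n = int(round((coverage[1] - coverage[0]) / bin_width))
    return coverage[0] + bin_width * np.arange(n + 1)


@dataclass
class SpikeCountTensor:
    """Binned spike counts for one recording session.

    counts : int array, units x trials x bins (10 ms bins)
    bin_edges : float array, bins + 1, seconds relative to stimulus onset
    trial_labels : list of ConditionLabel, one per trial
    unit_meta : DataFrame with columns mean_rate (Hz) and snr
    """

    counts: np.ndarray
    bin_edges: np.ndarray
    trial_labels: list[ConditionLabel]
    session_id: int = 0
    unit_meta: pd.DataFrame | None = None
    timeline: TrialTimeline = field(default_factory=TrialTimeline)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.validate()

    # -- shape helpers -------------------------------------------------
    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def task(self) -> str:
        return self.trial_labels[0].task

    def validate(self) -> None:
        if self.counts.ndim != 3:
            raise ValidationError("counts must be units x trials x bins")
        if np.any(self.counts < 0):
            u, t, b = np.argwhere(self.counts < 0)[0]
            raise ValidationError(f"negative count at unit {u}, trial {t}, bin {b}")
        if len(self.bin_edges) != self.n_bins + 1:
            raise ValidationError("bin_edges length must be bins + 1")
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValidationError("bins must be uniform")
        if len(self.trial_labels) != self.n_trials:
            raise ValidationError(
                f"{len(self.trial_labels)} trial labels for {self.n_trials} trials"
            )
        # balanced design: equal trial count per present condition
        counts = pd.Series(self.trial_labels).value_counts()
        if counts.nunique() > 1:
            bad = counts.idxmin()
            raise ValidationError(
                f"unbalanced trial counts: condition {bad} has {counts.min()} "
                f"trials, others up to {counts.max()} (session {self.session_id})"
            )
        if self.unit_meta is not None and len(self.unit_meta) != self.n_units:
            raise ValidationError("unit_meta length must equal number of units")

    # -- selection -----------------------------------------------------
    def trials_of(self, condition: ConditionLabel) -> np.ndarray:
        """Indices of trials with the given label."""
        return np.array([i for i, l in enumerate(self.trial_labels) if l == condition])

    def subset_units(self, mask: np.ndarray) -> "SpikeCountTensor":
        mask = np.asarray(mask)
        meta = None if self.unit_meta is None else self.unit_meta.loc[mask].reset_index(drop=True)
        return replace(self, counts=self.counts[mask], unit_meta=meta)

    def subset_trials(self, idx: np.ndarray) -> "SpikeCountTensor":
        labels = [self.trial_labels[i] for i in idx]
        return replace(self, counts=self.counts[:, idx], trial_labels=labels)

    def conditions(self) -> list[ConditionLabel]:
        """Conditions present, in canonical order."""
        present = set(self.trial_labels)
        return [c for c in condition_labels(self.task) if c in present]


def snap_window(window: tuple[float, float], bin_edges: np.ndarray
                ) -> tuple[int, int]:
    """Snap a time window outward to bin edges; return a bin slice (lo, hi).

    The window must lie within tensor coverage.  Snapping is outward and
    deterministic: the left edge moves to the nearest edge at or below it,
    the right edge to the nearest edge at or above it.
    """
    left, right = window
    if right <= left:
        raise ValueError(f"empty window {window}")
    eps = 1e-9
    if left < bin_edges[0] - eps or right > bin_edges[-1] + eps:
        raise ValueError(
            f"window {window} outside coverage "
            f"[{bin_edges[0]:g}, {bin_edges[-1]:g}]"
        )
    lo = int(np.searchsorted(bin_edges, left + eps, side="right") - 1)
    hi = int(np.searchsorted(bin_edges, right - eps, side="left"))
    lo = max(lo, 0)
    hi = min(hi, len(bin_edges) - 1)
    return lo, hi


def window_rate(tensor: SpikeCountTensor, window: tuple[float, float]
                ) -> np.ndarray:
    """Mean firing rate in Hz over a time window, per unit and trial.

    rate = total spike count in the window / window duration, where the
    window is snapped outward to bin edges.
    """
    lo, hi = snap_window(window, tensor.bin_edges)
    duration = tensor.bin_edges[hi] - tensor.bin_edges[lo]
    return tensor.counts[:, :, lo:hi].sum(axis=2) / duration


def select_units(tensor: SpikeCountTensor, min_rate: float = 0.5,
                 min_snr: float | None = 0.5) -> np.ndarray:
    """Unit-inclusion mask: mean rate > min_rate Hz and SNR > min_snr.

    SNR is carried as supplied metadata (it is waveform-derived upstream
    and cannot be recomputed from binned counts).  Pass ``min_snr=None``
    to disable the SNR criterion when metadata lack it.
    """
    if tensor.unit_meta is None or "mean_rate" not in tensor.unit_meta:
        total_dur = tensor.bin_edges[-1] - tensor.bin_edges[0]
        mean_rate = tensor.counts.sum(axis=(1, 2)) / (tensor.n_trials * total_dur)
    else:
        mean_rate = tensor.unit_meta["mean_rate"].to_numpy()
    mask = mean_rate > min_rate
    if min_snr is not None:
        if tensor.unit_meta is None or "snr" not in tensor.unit_meta:
            raise ValidationError(
                "unit_meta lacks 'snr'; supply SNR metadata or pass "
                "min_snr=None to disable the SNR criterion"
            )
        mask &= tensor.unit_meta["snr"].to_numpy() > min_snr
    return mask


def condition_response(tensor: SpikeCountTensor,
                       timeline: TrialTimeline | None = None) -> pd.DataFrame:
    """Mean rate per unit and condition over the analysis window (Hz).

    Returns a units x conditions DataFrame with columns in canonical
    condition order.
    """
    timeline = timeline or tensor.timeline
    rates = window_rate(tensor, timeline.analysis_window)
    conds = tensor.conditions()
    out = np.empty((tensor.n_units, len(conds)))
    for j, c in enumerate(conds):
        out[:, j] = rates[:, tensor.trials_of(c)].mean(axis=1)
    cols = [f"{c.sensory_field}:{c.touch_type}" for c in conds]
    return pd.DataFrame(out, columns=cols)
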