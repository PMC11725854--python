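"""HDF5 + CSV readers/writers for spike-count experiments.

Layout: one HDF5 group per session, ``/session_<id>/counts`` (uint16,
units x trials x bins), ``/session_<id>/bin_edges`` (float64 s), and
``/session_<id>/unit_meta/{mean_rate,snr}``.  Trial metadata travel in a
separate CSV with header ``session,trial,person,body_part,touch_type``.
Sessions are separate tensors because the recorded unit population is
re-sorted each day and unit counts differ across sessions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .data_model import (
    ConditionLabel,
    SpikeCountTensor,
    TrialTimeline,
    ValidationError,
)

TRIAL_COLUMNS = ["session", "trial", "person", "body_part", "touch_type"]


@dataclass
class Experiment:
    """A multi-session recording: one SpikeCountTensor per session."""

    sessions: list[SpikeCountTensor]
    task: str = "MSMT"
    truth: pd.DataFrame | None = field(default=None)  # generator ground truth

    @property
    def n_sessions(self) -> int:
        return len(self.sessions)

    @property
    def timeline(self) -> TrialTimeline:
        return self.sessions[0].timeline

    def total_units(self) -> int:
        return sum(s.n_units for s in self.sessions)


def save_dataset(exp: Experiment, h5_path, trial_csv_path) -> None:
    """Write counts to HDF5 and the trial table to CSV (bit-exact round-trip)."""
    rows = []
    with h5py.File(h5_path, "w") as f:
        f.attrs["task"] = exp.task
        f.attrs["timeline"] = json.dumps(exp.timeline.to_dict())
        for tensor in exp.sessions:
            g = f.create_group(f"session_{tensor.session_id}")
            g.create_dataset("counts", data=tensor.counts.astype(np.uint16))
            g.create_dataset("bin_edges", data=tensor.bin_edges.astype(np.float64))
            if tensor.unit_meta is not None:
                m = g.create_group("unit_meta")
                for col in tensor.unit_meta.columns:
                    m.create_dataset(col, data=tensor.unit_meta[col].to_numpy())
            for i, lab in enumerate(tensor.trial_labels):
                rows.append(
                    (tensor.session_id, i, lab.person, lab.body_part, lab.touch_type)
                )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(trial_csv_path, index=False)


def _parse_labels(df: pd.DataFrame, task: str) -> list[ConditionLabel]:
    labels = []
    for _, row in df.iterrows():
        try:
            labels.append(
                ConditionLabel(row["person"], row["body_part"], row["touch_type"], task)
            )
        except ValidationError as e:
            raise ValidationError(
                f"trial table row (session {row['session']}, trial {row['trial']}): {e}"
            ) from e
    return labels


def load_dataset(h5_path, trial_csv_path) -> Experiment:
    """Load and validate an experiment; inverse of :func:`save_dataset`.

    Raises :class:`ValidationError` naming the offending row/session on
    missing columns, labels outside the design enums, or unbalanced
    trial counts.
    """
    trials = pd.read_csv(trial_csv_path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial table missing columns: {missing}")
    sessions = []
    with h5py.File(h5_path, "r") as f:
        task = str(f.attrs.get("task", "MSMT"))
        timeline = TrialTimeline.from_dict(json.loads(f.attrs.get("timeline", "{}")))
        for name in sorted(f.keys(), key=lambda s: int(s.split("_")[1])):
            sid = int(name.split("_")[1])
            g = f[name]
            sub = trials[trials["session"] == sid].sort_values("trial")
            if len(sub) != g["counts"].shape[1]:
                raise ValidationError(
                    f"session {sid}: {len(sub)} trial rows for "
                    f"{g['counts'].shape[1]} trials in counts"
                )
            labels = _parse_labels(sub, task)
            meta = None
            if "unit_meta" in g:
                meta = pd.DataFrame(
                    {col: g["unit_meta"][col][()] for col in g["unit_meta"]}
                )
            try:
                tensor = SpikeCountTensor(
                    counts=g["counts"][()].astype(np.int64),
                    bin_edges=g["bin_edges"][()],
                    trial_labels=labels,
                    session_id=sid,
                    unit_meta=meta,
                    timeline=timeline,
                )
            except ValidationError as e:
                raise ValidationError(f"session {sid}: {e}") from e
            sessions.append(tensor)
    if not sessions:
        raise ValidationError("no sessions found in HDF5 file")
    return Experiment(sessions=sessions, task=task)


def save_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False)


def load_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)
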