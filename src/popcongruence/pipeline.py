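"""End-to-end orchestration: simulate -> analyze -> report.

A run is fully described by a :class:`RunConfig` (serializable JSON);
config + seed reproduce every output bit-exactly.  One global seed fans
out to per-stage child seeds through ``numpy.random.SeedSequence([seed,
stage_index])``, so any stage can be rerun in isolation with the same
stream.  Every output file is listed in a manifest with a SHA-256
content hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import decoding, io, models, popmetrics, subspace, synth, tuning
from .data_model import select_units

log = logging.getLogger("popcongruence")

STAGES = ("simulate", "tuning", "di", "corr", "decode", "models",
          "subspace", "axis_transfer")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (< 2**31)."""
    ss = np.random.SeedSequence([int(seed), STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    task: str = "MSMT"
    seed: int = 0
    out_dir: str = "popcongruence_run"
    n_units: int = 40
    n_sessions: int = 3
    trials_per_condition: int = 10
    model_mixture: dict | None = None
    q: float = 0.05
    n_resamples: int = 250          # split-half correlation
    cv_folds: int = 10
    decode_field: str = "Ac"
    decode_step: float = 0.01
    decode_stop: float = 3.0
    compositional: dict | None = None   # kwargs for CompositionalSpec
    stages: tuple[str, ...] = STAGES
    make_figures: bool = False

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["stages"] = tuple(d.get("stages", STAGES))
        if "model_mixture" in d and d["model_mixture"] is not None:
            d["model_mixture"] = dict(d["model_mixture"])
        return cls(**{k: v for k, v in d.items()
                      if k in {f.name for f in dataclasses.fields(cls)}})


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute the configured stages; return the manifest dict.

    Fails fast with the stage name on error; partial outputs are kept.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": json.loads(config.to_json()), "stages": {},
                      "files": {}}
    (out / "config.json").write_text(config.to_json())

    def record(stage: str, t0: float, files: list[Path]) -> None:
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 3)}
        for f in files:
            manifest["files"][str(f.relative_to(out))] = _sha256(f)

    exp = None
    selected = None
    try:
        # -- simulate ----------------------------------------------------
        stage = "simulate"
        t0 = time.time()
        if config.compositional is not None:
            cspec = synth.CompositionalSpec(
                n_units=config.n_units, n_sessions=config.n_sessions,
                trials_per_condition=config.trials_per_condition,
                seed=stage_seed(config.seed, stage), **config.compositional)
            exp, _ = synth.generate_compositional_population(cspec)
        else:
            pspec = synth.PopulationGenSpec(
                n_units=config.n_units, n_sessions=config.n_sessions,
                trials_per_condition=config.trials_per_condition,
                model_mixture=config.model_mixture,
                seed=stage_seed(config.seed, stage))
            exp = synth.generate_population(pspec, task=config.task)
        io.save_dataset(exp, out / "data.h5", out / "trials.csv")
        files = [out / "data.h5", out / "trials.csv"]
        if exp.truth is not None:
            io.save_truth(exp.truth, out / "truth.csv")
            files.append(out / "truth.csv")
        record(stage, t0, files)
        log.info("simulated %d sessions (%s)", exp.n_sessions, config.task)

        selected = [t.subset_units(select_units(t)) for t in exp.sessions]

        stage = "tuning"
        if "tuning" in config.stages:
            t0 = time.time()
            fits = [tuning.fit_session(t, q=config.q) for t in selected]
            frac = tuning.fraction_responsive(
                fits, seed=stage_seed(config.seed, "tuning"))
            frac.to_csv(out / "tuning_fraction_responsive.csv", index=False)
            record("tuning", t0, [out / "tuning_fraction_responsive.csv"])

        stage = "di"
        if "di" in config.stages:
            t0 = time.time()
            per, summary = popmetrics.di_summary(selected)
            per.to_csv(out / "di_sessions.csv", index=False)
            summary.to_csv(out / "di_summary.csv", index=False)
            record("di", t0, [out / "di_sessions.csv", out / "di_summary.csv"])

        stage = "corr"
        if "corr" in config.stages:
            t0 = time.time()
            seed = stage_seed(config.seed, "corr")
            mats = [popmetrics.splithalf_correlation(
                t, n_resamples=config.n_resamples, seed=seed + t.session_id)
                for t in selected]
            mean_r = np.mean([m.r for m in mats], axis=0)
            mats[0].to_frame().to_csv(out / "corr_session0.csv")
            pd.DataFrame(mean_r).to_csv(out / "corr_mean.csv")
            record("corr", t0, [out / "corr_session0.csv", out / "corr_mean.csv"])

        stage = "decode"
        if "decode" in config.stages and config.task == "MSMT":
            t0 = time.time()
            curve = decoding.time_resolved_accuracy(
                selected, field=config.decode_field, step=config.decode_step,
                stop=config.decode_stop)
            curve.summary().to_csv(out / "decoding_curve.csv", index=False)
            record("decode", t0, [out / "decoding_curve.csv"])

        stage = "models"
        if "models" in config.stages:
            t0 = time.time()
            mode = "binary" if config.task == "BSMT" else "sp_sharing"
            catalog = models.enumerate_models(4, mode)
            (out / "model_catalog.json").write_text(json.dumps(
                {m.model_id: str(m) for m in catalog}, indent=2))
            seed = stage_seed(config.seed, "models")
            frames = []
            for t in selected:
                resp = tuning.window_rate(t, t.timeline.analysis_window)
                base = tuning.window_rate(t, t.timeline.baseline_window)
                Y = resp - base.mean(axis=1, keepdims=True)
                best = models.select_best_population(
                    Y, t.trial_labels, catalog, cv_folds=config.cv_folds,
                    seed=seed + t.session_id)
                best["session"] = t.session_id
                frames.append(best)
            best_all = pd.concat(frames, ignore_index=True)
            best_all.to_csv(out / "model_best_per_unit.csv", index=False)
            hists = models.population_model_histogram(best_all)
            for name, df in hists.items():
                df.to_csv(out / f"model_hist_{name}.csv", index=False)
            record("models", t0, [out / "model_best_per_unit.csv",
                                  out / "model_catalog.json"] +
                   [out / f"model_hist_{n}.csv" for n in hists])

        sub_files = []
        stage = "subspace"
        if "subspace" in config.stages and config.task == "MSMT":
            t0 = time.time()
            seed = stage_seed(config.seed, "subspace")
            frames = []
            for t in selected:
                for heldout in ("person", "body_part"):
                    df = subspace.subspace_generalization(
                        t, heldout=heldout, seed=seed + t.session_id)
                    df["session"] = t.session_id
                    frames.append(df)
            gen = pd.concat(frames, ignore_index=True)
            gen.to_csv(out / "subspace_generalization.csv", index=False)
            sub_files.append(out / "subspace_generalization.csv")
            record("subspace", t0, sub_files)

        stage = "axis_transfer"
        if "axis_transfer" in config.stages and config.task == "MSMT":
            t0 = time.time()
            seed = stage_seed(config.seed, "axis_transfer")
            frames = []
            for t in selected:
                for info, across in (("touch_type", "person"),
                                     ("body_part", "person"),
                                     ("person", "body_part")):
                    df = subspace.axis_transfer_suite(
                        t, info, across, seed=seed + t.session_id)
                    df["session"] = t.session_id
                    frames.append(df)
            at = pd.concat(frames, ignore_index=True)
            at.to_csv(out / "axis_transfer.csv", index=False)
            record("axis_transfer", t0, [out / "axis_transfer.csv"])

        if config.make_figures:
            _make_figures(out)
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    return manifest


def _make_figures(out: Path) -> None:
    """Quick-look PNGs for whichever stage outputs exist."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    corr = out / "corr_mean.csv"
    if corr.exists():
        m = pd.read_csv(corr, index_col=0).to_numpy()
        fig, ax = plt.subplots(figsize=(4, 3.5))
        im = ax.imshow(m, vmin=-1, vmax=1, cmap="RdBu_r")
        fig.colorbar(im, ax=ax, label="r")
        ax.set_title("split-half condition correlation")
        fig.savefig(out / "corr_mean.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
    curve = out / "decoding_curve.csv"
    if curve.exists():
        df = pd.read_csv(curve)
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.plot(df["window_start"], df["accuracy"])
        ax.fill_between(df["window_start"], df["ci_lo"], df["ci_hi"], alpha=0.3)
        ax.axhline(0.25, ls="--", c="gray", lw=0.8)
        ax.set(xlabel="window start (s)", ylabel="accuracy",
               title="touch-type decoding")
        fig.savefig(out / "decoding_curve.png", dpi=120, bbox_inches="tight")
        plt.close(fig)
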