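"""Config-driven orchestration of the pipeline stages.

Every stage reads its inputs from the working directory, writes its artifacts
plus a ``<stage>_manifest.json`` recording the resolved parameters, the seed
and the package version, so each artifact is traceable to a configuration.
Stages: simulate -> preprocess -> {features -> baseline | train-cnn |
single-channel-scan | select-channels} -> report.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .baseline import FAMILIES, ClassifierSpec, crossval_classify
from .dataio import ChannelMontage, Recording, read_ratings, read_recording, write_ratings, write_recording
from .features import extract_features, feature_columns
from .nn import CNNConfig, build_model, evaluate, train, train_eval_masked
from .preprocess import (SplitSpec, balance, bandpass, common_average_reference,
                         label_trials, load_segments, save_segments, segment, split)
from .selection import CNNMaskEvaluator, ParetoFront, coincidence_tally, evolve, per_size_best
from .synthetic import SyntheticSpec, generate_cohort

STAGES = ("simulate", "preprocess", "features", "baseline", "train-cnn",
          "single-channel-scan", "select-channels", "report")


class RunConfig(BaseModel):
    """Resolved, fully serializable run configuration."""

    workdir: str
    seed: int = 0
    n_subjects: int = 1
    n_trials: int = 40
    fs: float = 128.0
    trial_seconds: float = 60.0
    effect_size: float = 1.0
    montage: list[str] | None = None
    arousal_channels: list[str] | None = None
    valence_channels: list[str] | None = None
    complementary: bool = False
    dimension: Literal["arousal", "valence"] = "arousal"
    seg_seconds: float = 2.0
    split_grouping: Literal["segment", "trial"] = "segment"
    band: tuple[float, float] = (4.0, 45.0)
    threshold: float = 5.0
    classifier_families: list[str] = Field(default_factory=lambda: list(FAMILIES))
    kfold: int = 10
    wavelet: str = "db4"
    kmax: int = 8
    cnn_profile: Literal["tiny", "full"] = "tiny"
    epochs: int | None = None
    pop_size: int = 10
    max_gen: int = 100
    tol: float = 0.001

    @field_validator("classifier_families")
    @classmethod
    def _known_families(cls, v):
        bad = [f for f in v if f not in FAMILIES]
        if bad:
            raise ValueError(f"unknown classifier families {bad}")
        return v

    def cnn_config(self) -> CNNConfig:
        if self.cnn_profile == "tiny":
            cfg = CNNConfig.tiny(fs=self.fs)
        else:
            cfg = CNNConfig(fs=self.fs)
        if self.epochs is not None:
            from dataclasses import replace
            cfg = replace(cfg, epochs=self.epochs)
        return cfg

    def synthetic_spec(self) -> SyntheticSpec:
        kw = {}
        montage = ChannelMontage(tuple(self.montage)) if self.montage else ChannelMontage.deap32()
        kw["montage"] = montage
        if self.arousal_channels is not None:
            kw["arousal_channels"] = tuple(self.arousal_channels)
        elif self.montage is not None:
            kw["arousal_channels"] = montage.names[:3]
        if self.valence_channels is not None:
            kw["valence_channels"] = tuple(self.valence_channels)
        elif self.montage is not None:
            kw["valence_channels"] = montage.names[3:6]
        return SyntheticSpec(n_trials=self.n_trials, fs=self.fs,
                             trial_seconds=self.trial_seconds,
                             effect_size=self.effect_size,
                             complementary=self.complementary,
                             seed=self.seed, **kw)


def _write_manifest(workdir: Path, stage: str, config: RunConfig, extra: dict | None = None) -> None:
    payload = {"stage": stage, "version": __version__, "seed": config.seed,
               "config": json.loads(config.model_dump_json())}
    payload.update(extra or {})
    blob = json.dumps(payload, indent=1, sort_keys=True)
    payload["config_hash"] = hashlib.sha256(blob.encode()).hexdigest()[:16]
    (workdir / f"{stage}_manifest.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def _subjects(config: RunConfig) -> list[str]:
    return [f"s{i + 1:02d}" for i in range(config.n_subjects)]


def _stem(config: RunConfig, subject: str) -> str:
    return f"{subject}_{config.dimension}_{config.seg_seconds:g}s"


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> None:
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    spec = config.synthetic_spec()
    bundles = generate_cohort(spec, config.n_subjects)
    truth_out = {}
    for rec, ratings, truth in bundles:
        write_recording(rec, workdir)
        write_ratings(ratings, workdir / f"{rec.subject_id}_ratings.csv", rec.subject_id)
        truth_out[rec.subject_id] = {
            "arousal_channels": list(truth.arousal_channels),
            "valence_channels": list(truth.valence_channels),
        }
    (workdir / "ground_truth.json").write_text(json.dumps(truth_out, indent=1))
    _write_manifest(workdir, "simulate", config)


def _preprocessed_recording(config: RunConfig, subject: str) -> Recording:
    workdir = Path(config.workdir)
    rec = read_recording(workdir / f"{subject}_recording.json")
    rec = bandpass(rec, *config.band)
    return common_average_reference(rec)


def stage_preprocess(config: RunConfig) -> None:
    workdir = Path(config.workdir)
    for subject in _subjects(config):
        rec = _preprocessed_recording(config, subject)
        ratings = read_ratings(workdir / f"{subject}_ratings.csv")
        labels = label_trials(ratings, config.dimension, config.threshold)
        retained = balance(labels, seed=config.seed)
        ds = segment(rec, retained, labels, config.seg_seconds, config.dimension)
        save_segments(ds, workdir, _stem(config, subject))
    _write_manifest(workdir, "preprocess", config)


def stage_features(config: RunConfig) -> None:
    workdir = Path(config.workdir)
    for subject in _subjects(config):
        ds = load_segments(workdir, _stem(config, subject))
        X = extract_features(ds, wavelet=config.wavelet, kmax=config.kmax)
        df = pd.DataFrame(X, columns=feature_columns(ds.montage.names))
        df.insert(0, "label", ds.y)
        df.to_csv(workdir / f"{_stem(config, subject)}_features.csv", index=False)
    _write_manifest(workdir, "features", config)


def stage_baseline(config: RunConfig) -> None:
    workdir = Path(config.workdir)
    rows = []
    for subject in _subjects(config):
        df = pd.read_csv(workdir / f"{_stem(config, subject)}_features.csv")
        y = df.pop("label").to_numpy()
        for family in config.classifier_families:
            rep = crossval_classify(df.to_numpy(), y, ClassifierSpec(family),
                                    k=config.kfold, seed=config.seed)
            rows.append({"subject": subject, "segment_s": config.seg_seconds,
                         "classifier": family, "mean_accuracy": rep.mean_accuracy,
                         "sd": rep.sd, "k_used": rep.k_used,
                         "chosen_params": json.dumps(rep.chosen_params)})
    pd.DataFrame(rows).to_csv(workdir / f"baseline_{config.dimension}.csv", index=False)
    _write_manifest(workdir, "baseline", config)


def stage_train_cnn(config: RunConfig) -> None:
    workdir = Path(config.workdir)
    cfg = config.cnn_config()
    rows = []
    for subject in _subjects(config):
        ds = load_segments(workdir, _stem(config, subject))
        tr, va, te = split(ds, SplitSpec(seed=config.seed, grouping=config.split_grouping))
        model = build_model(ds.n_channels, ds.n_samples, cfg, seed=config.seed)
        report = train(model, tr, va, cfg, seed=config.seed)
        acc = evaluate(model, te)
        curves = pd.DataFrame({"epoch": np.arange(1, len(report.train_accuracy) + 1),
                               "train_acc": report.train_accuracy,
                               "val_acc": report.val_accuracy})
        curves.to_csv(workdir / f"{_stem(config, subject)}_curves.csv", index=False)
        from .nn import save_checkpoint
        save_checkpoint(model, workdir / f"{_stem(config, subject)}_model.npz")
        rows.append({"subject": subject, "test_accuracy": acc,
                     "best_epoch": report.best_epoch})
    pd.DataFrame(rows).to_csv(workdir / f"cnn_{config.dimension}.csv", index=False)
    _write_manifest(workdir, "train-cnn", config)


def stage_single_channel_scan(config: RunConfig) -> None:
    workdir = Path(config.workdir)
    cfg = config.cnn_config()
    rows = []
    for subject in _subjects(config):
        ds = load_segments(workdir, _stem(config, subject))
        tr, va, te = split(ds, SplitSpec(seed=config.seed, grouping=config.split_grouping))
        for ci, label in enumerate(ds.montage.names):
            mask = np.zeros(ds.n_channels, dtype=bool)
            mask[ci] = True
            acc = train_eval_masked(tr, va, te, mask, cfg, seed=config.seed)
            rows.append({"subject": subject, "channel": label, "test_accuracy": acc})
    pd.DataFrame(rows).to_csv(workdir / f"single_channel_{config.dimension}.csv", index=False)
    _write_manifest(workdir, "single-channel-scan", config)


def stage_select_channels(config: RunConfig) -> None:
    workdir = Path(config.workdir)
    cfg = config.cnn_config()
    for subject in _subjects(config):
        ds = load_segments(workdir, _stem(config, subject))
        evaluator = CNNMaskEvaluator(
            ds, cfg, seed=config.seed,
            split_spec=SplitSpec(seed=config.seed, grouping=config.split_grouping))
        front, history = evolve(evaluator, n_genes=ds.n_channels,
                                pop_size=config.pop_size, max_gen=config.max_gen,
                                tol=config.tol, seed=config.seed)
        rows = [{"channels": ",".join(e.channel_labels(ds.montage)),
                 "accuracy": e.acc, "n_channels": e.n_channels}
                for e in front.entries]
        pd.DataFrame(rows).to_csv(
            workdir / f"{_stem(config, subject)}_front.csv", index=False)
        table = per_size_best(front)
        pd.DataFrame([{"n_channels": s, "accuracy": a} for s, a in table.items()]
                     ).to_csv(workdir / f"{_stem(config, subject)}_per_size.csv", index=False)
        hist = pd.DataFrame({
            "generation": np.arange(len(history.ideal)),
            "ideal_acc": [i[0] for i in history.ideal],
            "ideal_n": [i[1] for i in history.ideal],
            "nadir_acc": [n[0] for n in history.nadir],
            "nadir_n": [n[1] for n in history.nadir],
        })
        hist.to_csv(workdir / f"{_stem(config, subject)}_history.csv", index=False)
        _write_manifest(workdir, "select-channels", config,
                        {"subject": subject, "termination": history.termination,
                         "stopped_at": history.stopped_at,
                         "n_evaluations": evaluator.n_evaluations})


def stage_report(config: RunConfig) -> None:
    """Aggregate per-subject fronts into per-size tables and channel tallies."""
    workdir = Path(config.workdir)
    montage = None
    fronts: dict[tuple[str, str], ParetoFront] = {}
    per_size_rows = []
    for subject in _subjects(config):
        path = workdir / f"{_stem(config, subject)}_front.csv"
        if not path.exists():
            continue
        ds_meta = json.loads((workdir / f"{_stem(config, subject)}_meta.json").read_text())
        montage = ChannelMontage(tuple(ds_meta["montage"]))
        df = pd.read_csv(path)
        from .selection import ParetoEntry
        entries = []
        for _, row in df.iterrows():
            labels = str(row["channels"]).split(",")
            mask = tuple(1 if n in labels else 0 for n in montage.names)
            entries.append(ParetoEntry(mask, float(row["accuracy"]), int(row["n_channels"])))
        front = ParetoFront(entries)
        fronts[(subject, config.dimension)] = front
        row = {"subject": subject}
        row.update({f"n{s}": a for s, a in per_size_best(front).items()})
        per_size_rows.append(row)
    if not fronts:
        raise FileNotFoundError("no front CSVs found; run select-channels first")
    pd.DataFrame(per_size_rows).to_csv(
        workdir / f"report_per_size_{config.dimension}.csv", index=False)
    tally = coincidence_tally(fronts, montage)
    tally.to_csv(workdir / f"report_tally_{config.dimension}.csv")
    _write_manifest(workdir, "report", config)


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "features": stage_features,
    "baseline": stage_baseline,
    "train-cnn": stage_train_cnn,
    "single-channel-scan": stage_single_channel_scan,
    "select-channels": stage_select_channels,
    "report": stage_report,
}


def run_pipeline(config: RunConfig, stages: Sequence[str]) -> None:
    """Run the named stages in order; unknown stage names are rejected upfront."""
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stages {unknown}; valid: {list(_STAGE_FUNCS)}")
    for s in stages:
        _STAGE_FUNCS[s](config)
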