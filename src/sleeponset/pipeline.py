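"""End-to-end wiring: simulate -> extract -> select -> train -> classify.

Each stage reads/writes plain files (EDF/CSV recordings, CSV feature
matrices, a pickled model, JSON reports) so that runs are reproducible and
auditable: the resolved configuration is written next to every output and a
log records per-stage timings and warnings.  A single global seed fans out
deterministically to the stages that need randomness.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classification, selection, synth
from .errors import ValidationError
from .features import FEATURE_NAMES, feature_matrix
from .preprocessing import FilterSpec, bandpass
from .signal_io import Recording, read_recording, segment_epochs, write_recording

log = logging.getLogger("sleeponset")


@dataclass
class PipelineConfig:
    """All stage parameters in one validated, serialisable object."""

    epoch_s: float = 10.0
    resp_context_s: float = 60.0
    filter: FilterSpec = field(default_factory=FilterSpec)
    selection_k: int = 12
    selection_bins: int = 8
    sigma_grid: tuple = classification.DEFAULT_SIGMA_GRID
    c_grid: tuple = classification.DEFAULT_C_GRID
    cv_folds: int = 5
    prune_fraction: float = 0.30
    train_fraction: float = 0.70
    seed: int = 0
    version: str = "1"

    def validate(self) -> None:
        if not (1 <= self.selection_k <= len(FEATURE_NAMES)):
            raise ValidationError("selection_k outside 1..51")
        if not (0.0 < self.prune_fraction <= 1.0):
            raise ValidationError("prune_fraction outside (0, 1]")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValidationError("train_fraction outside (0, 1)")

    def stage_seed(self, stage: str) -> int:
        # deterministic fan-out of the global seed, kept below 2**31
        return (self.seed * 1_000_003 + sum(map(ord, stage))) % (2**31 - 1)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = FilterSpec(**{k.split(".", 1)[1]: v for k, v in raw.items() if k.startswith("filter.")})
        kwargs = {k: v for k, v in raw.items() if not k.startswith("filter.") and k in {f.name for f in dataclasses.fields(cls)}}
        cfg = cls(filter=filt, **kwargs)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        filt = d.pop("filter")
        d.update({f"filter.{k}": v for k, v in filt.items()})
        d["sigma_grid"] = list(self.sigma_grid)
        d["c_grid"] = list(self.c_grid)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _timed(stage: str):
    class _T:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("%s: start", stage)
            return self

        def __exit__(self, *exc):
            log.info("%s: done in %.2f s", stage, time.perf_counter() - self.t0)

    return _T()


def run_simulate(sim_config: synth.SimulationConfig, out_path, fmt: str = "edf") -> Recording:
    """Generate a labeled synthetic recording and write it (plus labels) to disk."""
    with _timed("simulate"):
        rec = synth.simulate(sim_config)
        write_recording(rec, out_path, fmt)
    return rec


def preprocess_recording(rec: Recording, config: PipelineConfig) -> Recording:
    """Band-pass the EEG channels; respiration passes through unchanged."""
    return Recording(
        eeg1=bandpass(rec.eeg1, rec.eeg_rate, config.filter),
        eeg2=bandpass(rec.eeg2, rec.eeg_rate, config.filter),
        resp=rec.resp,
        eeg_rate=rec.eeg_rate,
        resp_rate=rec.resp_rate,
        epoch_s=config.epoch_s,
        labels=rec.labels,
    )


def run_extract(recording_path, config: PipelineConfig, out_csv, fmt: str = "edf") -> pd.DataFrame:
    """Recording file -> filtered epochs -> 51-column feature CSV (+ label column)."""
    config.validate()
    with _timed("extract"):
        rec = read_recording(recording_path, fmt, epoch_s=config.epoch_s)
        filtered = preprocess_recording(rec, config)
        epochs = segment_epochs(filtered, config.resp_context_s)
        if not epochs:
            warnings.warn("recording shorter than one epoch; writing empty feature table")
            df = pd.DataFrame(columns=list(FEATURE_NAMES))
        else:
            df = feature_matrix(epochs, rec.eeg_rate)
        n_nan = int(df[list(FEATURE_NAMES)].isna().any(axis=1).sum()) if len(df) else 0
        if n_nan:
            log.warning("extract: %d epochs carry NaN-flagged features", n_nan)
        out_csv = Path(out_csv)
        df.to_csv(out_csv, index=False)
        config.to_yaml(out_csv.with_suffix(".config.yaml"))
    return df


def _contiguous_split(n: int, train_fraction: float) -> tuple[np.ndarray, np.ndarray]:
    """Leading block for training, trailing block for testing (no temporal leakage)."""
    n_train = int(round(train_fraction * n))
    idx = np.arange(n)
    return idx[:n_train], idx[n_train:]


def run_train(features_csv, config: PipelineConfig, out_dir) -> dict:
    """Feature CSV -> MI ranking, top-k selection, trained + pruned model, held-out report."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with _timed("train"):
        df = pd.read_csv(features_csv)
        if "label" not in df.columns:
            raise ValidationError("feature CSV has no 'label' column")
        labels = df["label"].to_numpy(dtype=int)
        tr, te = _contiguous_split(len(df), config.train_fraction)

        ranking = selection.rank_features(df.iloc[tr], labels[tr], config.selection_bins)
        ranking.to_frame().to_csv(out_dir / "mi_ranking.csv", index=False)
        selected = selection.select_top_k(ranking, config.selection_k)
        (out_dir / "selected_features.json").write_text(json.dumps(selected, indent=1))

        train_df = df.iloc[tr].dropna(subset=selected)
        model = classification.train(
            train_df,
            train_df["label"].to_numpy(dtype=int),
            feature_names=selected,
            sigma_grid=config.sigma_grid,
            c_grid=config.c_grid,
            folds=config.cv_folds,
            seed=config.stage_seed("train"),
        )
        pruned = classification.prune_support_vectors(model, config.prune_fraction)
        model.save(out_dir / "model.pkl")
        pruned.save(out_dir / "model_pruned.pkl")

        test_df = df.iloc[te].dropna(subset=selected)
        truth = classification.merge_levels(test_df["label"].to_numpy(dtype=int))
        report = classification.evaluate(classification.predict(model, test_df), truth)
        report_pruned = classification.evaluate(classification.predict(pruned, test_df), truth)

        report.confusion.to_csv(out_dir / "confusion_matrix.csv")
        summary = {
            "sigma": model.sigma,
            "C": model.C,
            "cv_accuracy": model.cv_accuracy,
            "selected_features": selected,
            "n_support_vectors": model.n_support_vectors,
            "n_support_vectors_pruned": pruned.n_support_vectors,
            "test": report.to_dict(),
            "test_pruned": report_pruned.to_dict(),
        }
        (out_dir / "report.json").write_text(json.dumps(summary, indent=1))
        config.to_yaml(out_dir / "config.yaml")
    return summary


def run_classify(model_path, recording_path, config: PipelineConfig, out_csv, fmt: str = "edf") -> pd.DataFrame:
    """Recording + trained model -> per-epoch class stream with alarm flags."""
    config.validate()
    with _timed("classify"):
        model = classification.VigilanceModel.load(model_path)
        rec = read_recording(recording_path, fmt, epoch_s=config.epoch_s)
        filtered = preprocess_recording(rec, config)
        epochs = segment_epochs(filtered, config.resp_context_s)
        df = feature_matrix(epochs, rec.eeg_rate)
        usable = df.dropna(subset=model.feature_names)
        preds = classification.predict(model, usable)
        out = pd.DataFrame(
            {
                "epoch_index": usable.index.to_numpy(),
                "predicted_class": preds,
                "alarm": [classification.alarm(int(p)) for p in preds],
            }
        )
        out_csv = Path(out_csv)
        out.to_csv(out_csv, index=False)
        config.to_yaml(out_csv.with_suffix(".config.yaml"))
    return out
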