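"""Canonical data model for DEAP-shaped EEG recordings and affect ratings.

A study works with per-subject :class:`Recording` tensors (trials x channels x
samples, microvolts) plus a :class:`RatingsTable` of continuous arousal/valence
self-reports on the 1-9 SAM scale.  On disk a recording is a ``.npy`` array with
a JSON sidecar declaring sampling rate, montage order and subject id, so the
montage position of every channel (and hence every chromosome gene downstream)
is fixed and serialized explicitly.
"""

from __future__ import annotations

import json
import pickle
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Channel order of the 32-electrode DEAP montage (10-20 system).  Gene ``i``
#: of a selection chromosome always refers to ``DEAP_MONTAGE_32[i]``.
DEAP_MONTAGE_32: tuple[str, ...] = (
    "Fp1", "AF3", "F3", "F7", "FC5", "FC1", "C3", "T7",
    "CP5", "CP1", "P3", "P7", "PO3", "O1", "Oz", "Pz",
    "Fp2", "AF4", "Fz", "F4", "F8", "FC6", "FC2", "C4",
    "T8", "CP6", "CP2", "P4", "P8", "PO4", "O2", "Cz",
)

RATING_MIN = 1.0
RATING_MAX = 9.0


class ShapeError(ValueError):
    """Raised when on-disk data disagrees with its declared layout."""


@dataclass(frozen=True)
class ChannelMontage:
    """Ordered, named electrode layout.

    The order is part of the study definition: chromosome gene positions,
    feature-column blocks and coincidence tallies all index into it.
    """

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("montage labels must be unique")
        if len(self.names) == 0:
            raise ValueError("montage must contain at least one channel")

    @classmethod
    def deap32(cls) -> "ChannelMontage":
        return cls(DEAP_MONTAGE_32)

    def __len__(self) -> int:
        return len(self.names)

    def index(self, label: str) -> int:
        try:
            return self.names.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def indices(self, labels: Iterable[str]) -> np.ndarray:
        return np.array([self.index(lbl) for lbl in labels], dtype=int)

    def subset(self, mask: Sequence[int] | np.ndarray) -> "ChannelMontage":
        """Montage restricted to channels where ``mask`` is truthy."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (len(self),):
            raise ShapeError(f"mask length {mask.shape} != montage size {len(self)}")
        return ChannelMontage(tuple(n for n, m in zip(self.names, mask) if m))


@dataclass
class Recording:
    """One subject's EEG: ``data[trial, channel, sample]`` in microvolts."""

    subject_id: str
    data: np.ndarray
    fs: float
    montage: ChannelMontage

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ShapeError(f"data must be 3-D (trials, channels, samples), got ndim={self.data.ndim}")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.data.shape[1] != len(self.montage):
            raise ShapeError(
                f"recording has {self.data.shape[1]} channels but montage declares {len(self.montage)}"
            )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def select_channels(self, mask: Sequence[int] | np.ndarray) -> "Recording":
        mask = np.asarray(mask, dtype=bool)
        return Recording(self.subject_id, self.data[:, mask, :], self.fs, self.montage.subset(mask))


@dataclass
class RatingsTable:
    """Per-trial arousal/valence self-reports, each in [1, 9]."""

    table: pd.DataFrame = field(repr=False)

    REQUIRED = ("trial", "arousal", "valence")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"ratings table missing columns: {missing}")
        for dim in ("arousal", "valence"):
            vals = self.table[dim].to_numpy(dtype=float)
            bad = (vals < RATING_MIN) | (vals > RATING_MAX) | ~np.isfinite(vals)
            if bad.any():
                raise ValueError(
                    f"{dim} ratings outside [{RATING_MIN}, {RATING_MAX}]: {vals[bad][:5]}"
                )
        self.table = self.table.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def values(self, dimension: str) -> np.ndarray:
        if dimension not in ("arousal", "valence"):
            raise ValueError(f"unknown dimension {dimension!r}")
        return self.table[dimension].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# on-disk round trip
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, directory: str | Path) -> Path:
    """Write ``<subject>_eeg.npy`` plus a JSON sidecar; returns the sidecar path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    data_name = f"{rec.subject_id}_eeg.npy"
    np.save(directory / data_name, rec.data)
    sidecar = {
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "montage": list(rec.montage.names),
        "data_file": data_name,
        "n_trials": rec.n_trials,
        "n_samples": rec.n_samples,
    }
    path = directory / f"{rec.subject_id}_recording.json"
    path.write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(sidecar_path: str | Path) -> Recording:
    """Read a recording from its JSON sidecar; fails loudly on shape mismatch."""
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise FileNotFoundError(sidecar_path)
    meta = json.loads(sidecar_path.read_text())
    data = np.load(sidecar_path.parent / meta["data_file"])
    montage = ChannelMontage(tuple(meta["montage"]))
    if data.ndim != 3 or data.shape[1] != len(montage):
        raise ShapeError(
            f"{meta['data_file']}: shape {data.shape} does not match montage of {len(montage)} channels"
        )
    if data.shape[0] != meta["n_trials"] or data.shape[2] != meta["n_samples"]:
        raise ShapeError(
            f"{meta['data_file']}: shape {data.shape} contradicts sidecar "
            f"({meta['n_trials']} trials x {meta['n_samples']} samples)"
        )
    return Recording(meta["subject_id"], data, float(meta["fs"]), montage)


def write_ratings(ratings: RatingsTable, path: str | Path, subject_id: str | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = ratings.table.copy()
    if subject_id is not None and "subject" not in df.columns:
        df.insert(0, "subject", subject_id)
    df.to_csv(path, index=False)
    return path


def read_ratings(path: str | Path) -> RatingsTable:
    """Read and validate a ratings CSV with columns trial, arousal, valence."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return RatingsTable(pd.read_csv(path))


def read_deap_dat(path: str | Path, montage: ChannelMontage | None = None,
                  fs: float = 128.0, trial_seconds: float = 60.0) -> tuple[Recording, RatingsTable]:
    """Optional adapter for DEAP's preprocessed pickled ``.dat`` files.

    DEAP stores ``data`` as 40 trials x 40 channels x 8064 samples (the first 32
    channels are EEG, the first 3 s are pre-trial baseline) and ``labels`` as
    40 x (valence, arousal, dominance, liking).  The canonical package format
    is the npy+JSON layout; this adapter only converts.
    """
    montage = montage or ChannelMontage.deap32()
    with open(path, "rb") as fh:
        blob = pickle.load(fh, encoding="latin1")
    data = np.asarray(blob["data"])[:, : len(montage), :]
    n_keep = int(round(fs * trial_seconds))
    data = data[:, :, -n_keep:]  # drop the 3-s pre-trial baseline
    labels = np.asarray(blob["labels"])
    subject = Path(path).stem
    rec = Recording(subject, data, fs, montage)
    ratings = RatingsTable(pd.DataFrame({
        "trial": np.arange(1, data.shape[0] + 1),
        "arousal": labels[:, 1],
        "valence": labels[:, 0],
    }))
    return rec, ratings
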