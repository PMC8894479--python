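"""Signal conditioning and dataset assembly.

Mirrors the standard affective-EEG protocol: band-pass 4-45 Hz, down-sample to
128 Hz, common average reference, binarize ratings at 5 into Low/High, balance
classes by dropping surplus trials, cut each 60-s trial into non-overlapping
segments of 2/5/10/60 s, and split instances 50/25/25 into train/validation/
test (class-stratified).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Literal, Sequence

import numpy as np
from scipy import signal as sps

from .dataio import ChannelMontage, Recording, RatingsTable

SEGMENT_SECONDS = (2, 5, 10, 60)

Dimension = Literal["arousal", "valence"]


@dataclass
class SegmentDataset:
    """Labeled fixed-length EEG segments with trial provenance.

    ``X[i]`` is one ``channels x seg_samples`` instance, ``y[i]`` its binary
    label (0 = Low, 1 = High on the chosen affect dimension), and
    ``trial_of[i]`` the source trial, so grouped splitting can keep sibling
    segments of one video together.
    """

    X: np.ndarray
    y: np.ndarray
    fs: float
    seg_seconds: float
    dimension: str
    trial_of: np.ndarray
    montage: ChannelMontage

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y, dtype=int)
        self.trial_of = np.asarray(self.trial_of, dtype=int)
        n = len(self.y)
        if self.X.shape[0] != n or self.trial_of.shape[0] != n:
            raise ValueError("X, y and trial_of must agree in length")
        if self.X.ndim != 3:
            raise ValueError("X must be (instances, channels, samples)")
        if int(round(self.seg_seconds * self.fs)) != self.X.shape[2]:
            raise ValueError("seg_samples must equal seg_seconds * fs")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]

    @property
    def n_samples(self) -> int:
        return self.X.shape[2]

    def subset(self, idx: np.ndarray) -> "SegmentDataset":
        return SegmentDataset(self.X[idx], self.y[idx], self.fs, self.seg_seconds,
                              self.dimension, self.trial_of[idx], self.montage)

    def select_channels(self, mask: Sequence[int] | np.ndarray) -> "SegmentDataset":
        mask = np.asarray(mask, dtype=bool)
        return SegmentDataset(self.X[:, mask, :], self.y, self.fs, self.seg_seconds,
                              self.dimension, self.trial_of, self.montage.subset(mask))


@dataclass(frozen=True)
class SplitSpec:
    """50/25/25 train/validation/test split specification."""

    fractions: tuple[float, float, float] = (0.50, 0.25, 0.25)
    seed: int = 0
    grouping: Literal["segment", "trial"] = "segment"

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


# ---------------------------------------------------------------------------
# filtering / referencing / resampling
# ---------------------------------------------------------------------------

def bandpass(rec: Recording, low_hz: float = 4.0, high_hz: float = 45.0,
             order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward-backward per trial/channel)."""
    if not (0 < low_hz < high_hz < rec.fs / 2):
        raise ValueError(f"band ({low_hz}, {high_hz}) invalid for fs={rec.fs}")
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.data, axis=-1)
    return Recording(rec.subject_id, out, rec.fs, rec.montage)


def resample(rec: Recording, target_hz: float = 128.0) -> Recording:
    """Polyphase rational resampling (anti-aliased); duration is preserved."""
    if target_hz <= 0:
        raise ValueError("target rate must be positive")
    if target_hz > rec.fs:
        raise ValueError("upsampling above the recorded rate is not supported")
    if target_hz == rec.fs:
        return rec
    frac = Fraction(target_hz / rec.fs).limit_denominator(1000)
    out = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=-1)
    return Recording(rec.subject_id, out, target_hz, rec.montage)


def common_average_reference(rec: Recording) -> Recording:
    """Subtract the instantaneous cross-channel mean from every channel."""
    if rec.n_channels < 2:
        raise ValueError("CAR needs at least two channels")
    out = rec.data - rec.data.mean(axis=1, keepdims=True)
    return Recording(rec.subject_id, out, rec.fs, rec.montage)


# ---------------------------------------------------------------------------
# labels / balancing / segmentation
# ---------------------------------------------------------------------------

def label_trials(ratings: RatingsTable, dimension: Dimension,
                 threshold: float = 5.0) -> np.ndarray:
    """Binarize ratings: ``< threshold`` -> 0 (Low), ``>= threshold`` -> 1 (High)."""
    vals = ratings.values(dimension)
    return (vals >= threshold).astype(int)


def balance(trial_labels: np.ndarray, seed: int = 0,
            strategy: Literal["random", "first"] = "random") -> np.ndarray:
    """Retain min(n_low, n_high) trials per class; returns sorted trial indices.

    Surplus trials of the majority class are dropped by seeded uniform sampling
    (default) or deterministically keeping the first k in trial order.
    """
    trial_labels = np.asarray(trial_labels, dtype=int)
    idx0 = np.flatnonzero(trial_labels == 0)
    idx1 = np.flatnonzero(trial_labels == 1)
    if len(idx0) == 0 or len(idx1) == 0:
        raise ValueError("both classes must be non-empty before balancing")
    k = min(len(idx0), len(idx1))
    if strategy == "first":
        keep = np.concatenate([idx0[:k], idx1[:k]])
    else:
        rng = np.random.default_rng(seed)
        keep = np.concatenate([
            rng.choice(idx0, size=k, replace=False),
            rng.choice(idx1, size=k, replace=False),
        ])
    return np.sort(keep)


def segment(rec: Recording, retained: np.ndarray, trial_labels: np.ndarray,
            seg_seconds: float, dimension: str = "arousal") -> SegmentDataset:
    """Cut retained trials into non-overlapping ``seg_seconds`` instances.

    Each 60-s trial yields ``floor(trial_seconds / seg_seconds)`` instances
    inheriting the trial label, e.g. 38 balanced trials -> 1140 two-second
    instances.
    """
    retained = np.asarray(retained, dtype=int)
    trial_labels = np.asarray(trial_labels, dtype=int)
    seg_samples = int(round(seg_seconds * rec.fs))
    trial_seconds = rec.n_samples / rec.fs
    n_per_trial = rec.n_samples // seg_samples
    if n_per_trial < 1 or rec.n_samples % seg_samples != 0:
        raise ValueError(
            f"segment length {seg_seconds}s does not divide trial duration {trial_seconds}s"
        )
    X, y, trial_of = [], [], []
    for t in retained:
        trial = rec.data[t]
        for j in range(n_per_trial):
            X.append(trial[:, j * seg_samples:(j + 1) * seg_samples])
            y.append(trial_labels[t])
            trial_of.append(t)
    return SegmentDataset(np.stack(X), np.array(y), rec.fs, seg_seconds,
                          dimension, np.array(trial_of), rec.montage)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def _allocate(n: int, fractions: Sequence[float], rotate: int) -> list[int]:
    # largest-remainder quota allocation; remainder ties broken by a rotation
    # so aggregated partition sizes land on the declared fractions exactly
    base = [int(np.floor(f * n)) for f in fractions]
    leftover = n - sum(base)
    rema = [(f * n) - b for f, b in zip(fractions, base)]
    order = sorted(range(len(fractions)), key=lambda i: (-rema[i], (i + rotate) % len(fractions)))
    for i in order[:leftover]:
        base[i] += 1
    return base


def split_indices(y: np.ndarray, trial_of: np.ndarray, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Class-stratified disjoint/exhaustive index partition at spec fractions.

    ``grouping='trial'`` assigns whole trials to partitions so no video
    contributes segments to two partitions.
    """
    y = np.asarray(y, dtype=int)
    trial_of = np.asarray(trial_of, dtype=int)
    rng = np.random.default_rng(spec.seed)
    parts: list[list[int]] = [[], [], []]
    classes = np.unique(y)
    if spec.grouping == "segment":
        for ci, c in enumerate(classes):
            idx = np.flatnonzero(y == c)
            idx = rng.permutation(idx)
            sizes = _allocate(len(idx), spec.fractions, rotate=ci)
            splits = np.split(idx, np.cumsum(sizes)[:-1])
            for p, s in zip(parts, splits):
                p.extend(s.tolist())
    else:
        for ci, c in enumerate(classes):
            trials = np.unique(trial_of[y == c])
            trials = rng.permutation(trials)
            sizes = _allocate(len(trials), spec.fractions, rotate=ci)
            tsplits = np.split(trials, np.cumsum(sizes)[:-1])
            for p, ts in zip(parts, tsplits):
                p.extend(np.flatnonzero(np.isin(trial_of, ts) & (y == c)).tolist())
    out = tuple(np.sort(np.array(p, dtype=int)) for p in parts)
    for p in out:
        if len(p) == 0:
            raise ValueError("too few instances: an empty partition was produced")
    return out


def split(ds: SegmentDataset, spec: SplitSpec) -> tuple[SegmentDataset, SegmentDataset, SegmentDataset]:
    tr, va, te = split_indices(ds.y, ds.trial_of, spec)
    return ds.subset(tr), ds.subset(va), ds.subset(te)


def save_segments(ds: SegmentDataset, directory, stem: str) -> None:
    """Serialize as ``<stem>_X.npy`` + label/provenance CSV + JSON meta."""
    import json
    from pathlib import Path

    import pandas as pd

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.save(directory / f"{stem}_X.npy", ds.X)
    pd.DataFrame({"label": ds.y, "trial": ds.trial_of}).to_csv(
        directory / f"{stem}_labels.csv", index=False)
    (directory / f"{stem}_meta.json").write_text(json.dumps({
        "fs": ds.fs, "seg_seconds": ds.seg_seconds, "dimension": ds.dimension,
        "montage": list(ds.montage.names),
    }))


def load_segments(directory, stem: str) -> SegmentDataset:
    import json
    from pathlib import Path

    import pandas as pd

    directory = Path(directory)
    X = np.load(directory / f"{stem}_X.npy")
    tab = pd.read_csv(directory / f"{stem}_labels.csv")
    meta = json.loads((directory / f"{stem}_meta.json").read_text())
    return SegmentDataset(X, tab["label"].to_numpy(), meta["fs"], meta["seg_seconds"],
                          meta["dimension"], tab["trial"].to_numpy(),
                          ChannelMontage(tuple(meta["montage"])))


def adjust_kfold(n_instances: int, k: int = 10) -> int:
    """Shrink k to the instance count when a subject has fewer than k instances."""
    if n_instances < 2:
        raise ValueError("cross-validation needs at least 2 instances")
    return min(k, n_instances)
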