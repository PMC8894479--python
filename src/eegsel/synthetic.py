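"""Seeded generator of DEAP-shaped EEG with known informative channels.

Each synthetic subject mimics the shape of the public affective-EEG datasets:
40 one-minute trials, 32 named 10-20 channels, 128 Hz, continuous
arousal/valence self-reports in [1, 9].  The background on every channel is
1/f^beta (pink) noise.  On a small, known set of *informative* channels a
band-limited oscillation is planted whose amplitude grows with the rating's
distance above the class threshold: alpha (10 Hz) for arousal, beta (20 Hz) on
a disjoint channel set for valence, so the two dimensions are separable tasks.

The generator exists to make channel recovery falsifiable — a selection
algorithm should find the planted channels and nothing else — not to mimic
real-EEG statistics.  With ``effect_size = 0`` the classes are statistically
identical and any classifier must sit at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import ChannelMontage, Recording, RatingsTable

ALPHA_HZ = 10.0   # arousal carrier, inside the 8-12 Hz alpha band
BETA_HZ = 20.0    # valence carrier, inside the 16-24 Hz beta band


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic cohort.

    ``effect_size`` scales the planted oscillation amplitude:
    ``amplitude = modulation_uv * effect_size * max(0, rating - 5)`` microvolts,
    on top of pink noise of standard deviation ``noise_uv``.  ``class_counts``
    optionally fixes the exact number of (low, high) trials per dimension, in
    which case ratings are drawn from the separated uniform ranges
    ``low_rating_range`` / ``high_rating_range``; otherwise ratings are iid
    uniform on [1, 9].  Narrowing the high range away from the threshold
    yields homogeneous burst amplitudes, the regime for unambiguous
    channel-recovery experiments.

    With ``complementary`` each expressing trial is divided into k contiguous
    time blocks (k = number of informative channels) and block j carries the
    oscillation on informative channel j only (rotated per trial), so any
    single channel sees the cue in only 1/k of a trial's segments and only the
    full planted set is sufficient — the regime in which subset selection of
    size k is non-trivial.  By default the oscillation is redundant: present
    on every informative channel for the whole trial, so even one of them can
    saturate accuracy.
    """

    n_trials: int = 40
    fs: float = 128.0
    trial_seconds: float = 60.0
    montage: ChannelMontage = field(default_factory=ChannelMontage.deap32)
    arousal_channels: tuple[str, ...] = ("C4", "AF4", "O1")
    valence_channels: tuple[str, ...] = ("PO3", "Oz", "Fp2")
    effect_size: float = 1.0
    modulation_uv: float = 2.0
    noise_uv: float = 10.0
    noise_exponent: float = 1.0
    class_counts: Mapping[str, tuple[int, int]] | None = None
    low_rating_range: tuple[float, float] = (1.5, 4.5)
    high_rating_range: tuple[float, float] = (5.5, 8.5)
    min_per_class: int = 2
    complementary: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        for ch in (*self.arousal_channels, *self.valence_channels):
            self.montage.index(ch)  # KeyError if absent


@dataclass
class GroundTruth:
    """What the generator planted: informative channels and implied labels."""

    arousal_channels: tuple[str, ...]
    valence_channels: tuple[str, ...]
    labels: dict[str, np.ndarray]  # dimension -> per-trial 0/1


def _pink_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """1/f^exponent amplitude-shaped Gaussian noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _draw_ratings(rng: np.random.Generator, spec: SyntheticSpec, dimension: str) -> np.ndarray:
    counts = (spec.class_counts or {}).get(dimension)
    if counts is not None:
        n_low, n_high = counts
        if n_low + n_high != spec.n_trials:
            raise ValueError(f"class counts {counts} must sum to n_trials={spec.n_trials}")
        r = np.concatenate([rng.uniform(*spec.low_rating_range, size=n_low),
                            rng.uniform(*spec.high_rating_range, size=n_high)])
        return rng.permutation(r)
    for _ in range(1000):
        r = rng.uniform(1.0, 9.0, size=spec.n_trials)
        n_low = int((r < 5.0).sum())
        if min(n_low, spec.n_trials - n_low) >= spec.min_per_class:
            return r
    raise RuntimeError("could not draw ratings satisfying min_per_class")


def generate_subject(spec: SyntheticSpec, subject_id: str = "s01",
                     seed: int | None = None) -> tuple[Recording, RatingsTable, GroundTruth]:
    """One subject's recording, ratings and planted ground truth (seeded)."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n_samp = int(round(spec.fs * spec.trial_seconds))
    n_ch = len(spec.montage)
    arousal = _draw_ratings(rng, spec, "arousal")
    valence = _draw_ratings(rng, spec, "valence")

    data = np.empty((spec.n_trials, n_ch, n_samp))
    t = np.arange(n_samp) / spec.fs
    planted = {
        "arousal": (spec.montage.indices(spec.arousal_channels), ALPHA_HZ, arousal),
        "valence": (spec.montage.indices(spec.valence_channels), BETA_HZ, valence),
    }
    for trial in range(spec.n_trials):
        for c in range(n_ch):
            data[trial, c] = spec.noise_uv * _pink_noise(rng, n_samp, spec.noise_exponent)
        for dim, (idx, freq, ratings) in planted.items():
            amp = spec.modulation_uv * spec.effect_size * max(0.0, ratings[trial] - 5.0)
            if amp == 0.0:
                continue
            if spec.complementary:
                k = len(idx)
                edges = np.linspace(0, n_samp, k + 1).astype(int)
                for j in range(k):
                    c = idx[(j + trial) % k]
                    sl = slice(edges[j], edges[j + 1])
                    phase = rng.uniform(0, 2 * np.pi)
                    data[trial, c, sl] += amp * np.sin(2 * np.pi * freq * t[sl] + phase)
            else:
                for c in idx:
                    phase = rng.uniform(0, 2 * np.pi)
                    data[trial, c] += amp * np.sin(2 * np.pi * freq * t + phase)

    rec = Recording(subject_id, data, spec.fs, spec.montage)
    ratings = RatingsTable(pd.DataFrame({
        "trial": np.arange(1, spec.n_trials + 1),
        "arousal": arousal,
        "valence": valence,
    }))
    truth = GroundTruth(spec.arousal_channels, spec.valence_channels,
                        {"arousal": (arousal >= 5.0).astype(int),
                         "valence": (valence >= 5.0).astype(int)})
    return rec, ratings, truth


def generate_cohort(spec: SyntheticSpec, n_subjects: int,
                    jitter_informative: bool = False
                    ) -> list[tuple[Recording, RatingsTable, GroundTruth]]:
    """Independent seeded subjects sharing the montage and planted channels.

    With ``jitter_informative`` each subject swaps at most one informative
    channel (per dimension) for a random non-informative one, emulating
    inter-subject variability in the relevant scalp sites.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    master = np.random.SeedSequence(spec.seed)
    sub_seeds = master.spawn(n_subjects)
    out = []
    for i, ss in enumerate(sub_seeds):
        child = np.random.default_rng(ss)
        sub_spec = spec
        if jitter_informative:
            sub_spec = replace(spec,
                               arousal_channels=_jitter(child, spec, spec.arousal_channels),
                               valence_channels=_jitter(child, spec, spec.valence_channels))
        sub_seed = int(child.integers(2 ** 31))
        out.append(generate_subject(sub_spec, subject_id=f"s{i + 1:02d}", seed=sub_seed))
    return out


def _jitter(rng: np.random.Generator, spec: SyntheticSpec,
            channels: tuple[str, ...]) -> tuple[str, ...]:
    used = set(spec.arousal_channels) | set(spec.valence_channels)
    free = [c for c in spec.montage.names if c not in used]
    if rng.random() < 0.5 or not free:
        return channels
    out = list(channels)
    out[rng.integers(len(out))] = free[rng.integers(len(free))]
    return tuple(out)
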