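"""Wavelet sub-band features for the classical-classifier baseline.

Each channel of a segment is decomposed with a 4-level DWT (Daubechies-4 by
default) into five sub-bands (A4, D4, D3, D2, D1).  Per sub-band, four scalar
features are computed — Teager energy, instantaneous energy, Higuchi fractal
dimension and Petrosian fractal dimension — giving 5 x 4 = 20 features per
channel.

Both energy features are reported on a log10 scale, so scaling a signal by c
shifts them by exactly 2*log10(c).  All-zero (degenerate) sub-bands are kept
finite by clamping log arguments at ``LOG_EPS``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .preprocess import SegmentDataset

LOG_EPS = 1e-12

FEATURE_NAMES = ("teager", "instantaneous", "higuchi", "petrosian")
N_FEATURES_PER_BAND = len(FEATURE_NAMES)
N_LEVELS = 4
N_BANDS = N_LEVELS + 1  # A4, D4, D3, D2, D1
N_FEATURES_PER_CHANNEL = N_BANDS * N_FEATURES_PER_BAND  # 20


@dataclass
class WaveletDecomposition:
    """Ordered sub-band coefficients of an L-level DWT: [A_L, D_L, ..., D_1]."""

    subbands: list[np.ndarray]
    wavelet_name: str
    levels: int

    @property
    def band_names(self) -> list[str]:
        return [f"A{self.levels}"] + [f"D{k}" for k in range(self.levels, 0, -1)]

    def reconstruct(self) -> np.ndarray:
        return pywt.waverec(self.subbands, self.wavelet_name, mode="symmetric")


def dwt_decompose(x: np.ndarray, levels: int = N_LEVELS, wavelet: str = "db4") -> WaveletDecomposition:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("signal must be 1-D")
    if len(x) < 2 ** levels:
        raise ValueError(f"signal of length {len(x)} too short for {levels} levels")
    coeffs = pywt.wavedec(x, wavelet, mode="symmetric", level=levels)
    return WaveletDecomposition(list(coeffs), wavelet, levels)


# ---------------------------------------------------------------------------
# per-sub-band features
# ---------------------------------------------------------------------------

def instantaneous_energy(c: np.ndarray) -> float:
    """log10 of the mean squared coefficient."""
    c = np.asarray(c, dtype=float)
    if c.size == 0:
        raise ValueError("empty coefficient sequence")
    return float(np.log10(max(np.mean(c ** 2), LOG_EPS)))


def teager_energy(c: np.ndarray) -> float:
    """log10 of the mean absolute Teager operator, |c_i^2 - c_{i-1} c_{i+1}|."""
    c = np.asarray(c, dtype=float)
    if c.size < 3:
        raise ValueError("Teager energy needs at least 3 samples")
    op = np.abs(c[1:-1] ** 2 - c[:-2] * c[2:])
    return float(np.log10(max(np.mean(op), LOG_EPS)))


def higuchi_fd(c: np.ndarray, kmax: int = 8) -> float:
    """Higuchi fractal dimension: slope of log L(k) against log(1/k).

    L(k) is the mean normalized curve length over the k down-sampled
    sub-series starting at offsets m = 0..k-1.  Returns 1.0 for degenerate
    (zero curve length) input; ~1 for smooth curves, ~2 for white noise.
    """
    c = np.asarray(c, dtype=float)
    if kmax < 2:
        raise ValueError("kmax must be >= 2")
    n = c.size
    if n < 2 * kmax:
        raise ValueError(f"sequence of length {n} too short for kmax={kmax}")
    lk = np.empty(kmax - 1)
    ks = np.arange(2, kmax + 1)
    for i, k in enumerate(ks):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if len(idx) < 2:
                continue
            dist = np.abs(np.diff(c[idx])).sum()
            norm = (n - 1) / (len(idx) - 1) / k
            lengths.append(dist * norm / k)
        lk[i] = np.mean(lengths)
    if np.any(lk <= 0):
        return 1.0
    slope, _ = np.polyfit(np.log(1.0 / ks), np.log(lk), 1)
    return float(slope)


def petrosian_fd(c: np.ndarray) -> float:
    """Petrosian fractal dimension from sign changes of the first difference.

    PFD = log10(N) / (log10(N) + log10(N / (N + 0.4 * N_delta))) where N_delta
    counts sign changes in diff(c).  Constant and monotone sequences give
    exactly 1.0.
    """
    c = np.asarray(c, dtype=float)
    n = c.size
    if n < 3:
        raise ValueError("Petrosian FD needs at least 3 samples")
    d = np.diff(c)
    s = np.sign(d)
    n_delta = int(np.count_nonzero(s[:-1] * s[1:] < 0))
    logn = np.log10(n)
    return float(logn / (logn + np.log10(n / (n + 0.4 * n_delta))))


_FEATURE_FUNCS = {
    "teager": teager_energy,
    "instantaneous": instantaneous_energy,
    "higuchi": higuchi_fd,
    "petrosian": petrosian_fd,
}


def channel_features(x: np.ndarray, wavelet: str = "db4", kmax: int = 8,
                     levels: int = N_LEVELS) -> np.ndarray:
    """The 20-vector for one channel: sub-band-major, feature-minor order."""
    dec = dwt_decompose(x, levels=levels, wavelet=wavelet)
    out = np.empty(len(dec.subbands) * N_FEATURES_PER_BAND)
    i = 0
    for band in dec.subbands:
        out[i] = teager_energy(band)
        out[i + 1] = instantaneous_energy(band)
        out[i + 2] = higuchi_fd(band, kmax=kmax)
        out[i + 3] = petrosian_fd(band)
        i += N_FEATURES_PER_BAND
    return out


def feature_columns(montage_names, levels: int = N_LEVELS) -> list[str]:
    bands = [f"A{levels}"] + [f"D{k}" for k in range(levels, 0, -1)]
    return [f"{ch}_{b}_{f}" for ch in montage_names for b in bands for f in FEATURE_NAMES]


def extract_features(ds: SegmentDataset, wavelet: str = "db4", kmax: int = 8,
                     levels: int = N_LEVELS) -> np.ndarray:
    """Feature matrix of shape (n_instances, n_channels * 20).

    Column order is channel-major (montage order), then sub-band A4..D1, then
    (teager, instantaneous, higuchi, petrosian); see :func:`feature_columns`.
    """
    n, c = len(ds), ds.n_channels
    out = np.empty((n, c * N_BANDS * N_FEATURES_PER_BAND))
    width = N_BANDS * N_FEATURES_PER_BAND
    for i in range(n):
        for j in range(c):
            out[i, j * width:(j + 1) * width] = channel_features(
                ds.X[i, j], wavelet=wavelet, kmax=kmax, levels=levels)
    return out
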