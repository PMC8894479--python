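import numpy as np
import pytest

from eegsel.dataio import ChannelMontage, DEAP_MONTAGE_32
from eegsel.preprocess import SegmentDataset


@pytest.fixture(scope="session")
def montage8() -> ChannelMontage:
    """Reduced 8-channel montage used by the desk-scale experiments."""
    return ChannelMontage(DEAP_MONTAGE_32[:8])


def separable_segments(n_per_class: int = 20, n_channels: int = 2,
                       n_samples: int = 128, fs: float = 64.0,
                       seed: int = 0) -> SegmentDataset:
    """Trivially separable two-class segments: class 1 carries a strong tone."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / fs
    X = rng.standard_normal((2 * n_per_class, n_channels, n_samples))
    y = np.repeat([0, 1], n_per_class)
    X[y == 1] += 8.0 * np.sin(2 * np.pi * 8.0 * t)
    order = rng.permutation(len(y))
    montage = ChannelMontage(tuple(DEAP_MONTAGE_32[:n_channels]))
    return SegmentDataset(X[order], y[order], fs, n_samples / fs, "arousal",
                          np.arange(len(y))[order], montage)
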