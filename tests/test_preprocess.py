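import numpy as np
import pandas as pd
import pytest

from eegsel.dataio import ChannelMontage, Recording, RatingsTable
from eegsel.preprocess import (SegmentDataset, SplitSpec, adjust_kfold, balance,
                               bandpass, common_average_reference, label_trials,
                               load_segments, resample, save_segments, segment,
                               split, split_indices)


def _tone_recording(freq_hz: float, fs: float = 128.0, seconds: float = 4.0,
                    n_channels: int = 2) -> Recording:
    t = np.arange(int(fs * seconds)) / fs
    x = np.sin(2 * np.pi * freq_hz * t)
    data = np.tile(x, (1, n_channels, 1))
    montage = ChannelMontage(tuple(f"ch{i}" for i in range(n_channels)))
    return Recording("s01", data, fs, montage)


def _rms(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean(x ** 2)))


class TestBandpass:
    def test_stopband_tone_attenuated(self):
        rec = _tone_recording(2.0)
        out = bandpass(rec)
        assert _rms(out.data) < 0.1 * _rms(rec.data)

    def test_passband_tone_preserved(self):
        rec = _tone_recording(10.0)
        out = bandpass(rec)
        assert abs(_rms(out.data) - _rms(rec.data)) < 0.05 * _rms(rec.data)

    def test_stopband_vs_passband_ratio_at_least_10x(self):
        low = bandpass(_tone_recording(2.0))
        mid = bandpass(_tone_recording(10.0))
        assert _rms(mid.data) / _rms(low.data) >= 10.0

    def test_zero_signal_stays_zero(self):
        rec = Recording("s", np.zeros((1, 2, 512)), 128.0,
                        ChannelMontage(("a", "b")))
        assert np.allclose(bandpass(rec).data, 0.0)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(_tone_recording(10.0), low_hz=4.0, high_hz=80.0)


class TestResample:
    def test_512hz_minute_trial_gives_7680_samples(self):
        fs = 512.0
        data = np.zeros((1, 2, int(fs * 60)))
        rec = Recording("s", data, fs, ChannelMontage(("a", "b")))
        out = resample(rec, 128.0)
        assert out.n_samples == 128 * 60 == 7680
        assert out.fs == 128.0

    def test_identity_when_target_equals_fs(self):
        rec = _tone_recording(10.0)
        assert resample(rec, rec.fs) is rec

    def test_spectral_peak_preserved(self):
        fs = 256.0
        t = np.arange(int(fs * 4)) / fs
        data = np.sin(2 * np.pi * 10.0 * t)[None, None, :]
        rec = Recording("s", np.tile(data, (1, 2, 1)), fs, ChannelMontage(("a", "b")))
        out = resample(rec, 128.0)
        spec = np.abs(np.fft.rfft(out.data[0, 0]))
        freqs = np.fft.rfftfreq(out.n_samples, d=1 / 128.0)
        assert abs(freqs[np.argmax(spec)] - 10.0) < 0.5

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample(_tone_recording(10.0, fs=128.0), 256.0)


class TestCommonAverageReference:
    def test_per_sample_channel_mean_vanishes(self):
        rng = np.random.default_rng(0)
        rec = Recording("s", rng.standard_normal((3, 8, 256)), 128.0,
                        ChannelMontage(tuple(f"c{i}" for i in range(8))))
        out = common_average_reference(rec)
        assert np.abs(out.data.mean(axis=1)).max() < 1e-10

    def test_zero_mean_input_unchanged(self):
        data = np.stack([np.ones((1, 256)), -np.ones((1, 256))], axis=1)
        rec = Recording("s", data, 128.0, ChannelMontage(("a", "b")))
        np.testing.assert_allclose(common_average_reference(rec).data, rec.data)

    def test_single_channel_rejected(self):
        rec = Recording("s", np.zeros((1, 1, 64)), 128.0, ChannelMontage(("a",)))
        with pytest.raises(ValueError):
            common_average_reference(rec)


class TestLabeling:
    @pytest.mark.parametrize("rating,expected", [(4.99, 0), (5.0, 1), (1.0, 0), (9.0, 1)])
    def test_threshold_rule(self, rating, expected):
        t = RatingsTable(pd.DataFrame({"trial": [1], "arousal": [rating], "valence": [5.0]}))
        assert label_trials(t, "arousal")[0] == expected

    def test_all_high_ratings(self):
        t = RatingsTable(pd.DataFrame({"trial": range(5), "arousal": [9.0] * 5,
                                       "valence": [9.0] * 5}))
        assert label_trials(t, "valence").sum() == 5


class TestBalance:
    def test_19_25_keeps_19_per_class(self):
        labels = np.array([0] * 19 + [1] * 25)
        keep = balance(labels, seed=0)
        assert len(keep) == 38
        assert (labels[keep] == 0).sum() == 19
        assert (labels[keep] == 1).sum() == 19

    def test_already_balanced_keeps_all(self):
        labels = np.array([0] * 10 + [1] * 10)
        assert len(balance(labels, seed=0)) == 20

    def test_extreme_imbalance_min_rule(self):
        labels = np.array([0] + [1] * 39)
        keep = balance(labels, seed=0)
        assert len(keep) == 2

    def test_no_duplicates(self):
        labels = np.array([0] * 7 + [1] * 13)
        keep = balance(labels, seed=3)
        assert len(np.unique(keep)) == len(keep)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            balance(np.ones(10, dtype=int), seed=0)


class TestSegmentation:
    @pytest.fixture()
    def rec38(self):
        montage = ChannelMontage(("a", "b"))
        data = np.arange(40 * 2 * 7680, dtype=float).reshape(40, 2, 7680)
        return Recording("s01", data, 128.0, montage)

    @pytest.mark.parametrize("seg_s,expected", [(2, 1140), (5, 456), (10, 228), (60, 38)])
    def test_worked_example_instance_counts(self, rec38, seg_s, expected):
        # 38 balanced 60-s trials -> 228/456/1140 instances at 10/5/2 s
        labels = np.array([0, 1] * 20)
        retained = np.arange(38)
        ds = segment(rec38, retained, labels, seg_s)
        assert len(ds) == expected
        assert len(ds) == 38 * (60 // seg_s)

    def test_single_trial_60s_single_instance(self, rec38):
        ds = segment(rec38, np.array([5]), np.ones(40, dtype=int), 60)
        assert len(ds) == 1
        assert ds.n_samples == 7680

    def test_labels_and_provenance_inherited(self, rec38):
        labels = np.zeros(40, dtype=int)
        labels[7] = 1
        ds = segment(rec38, np.array([3, 7]), labels, 10)
        assert set(ds.trial_of) == {3, 7}
        assert all(ds.y[ds.trial_of == 7] == 1)
        # segments tile the trial without overlap
        np.testing.assert_array_equal(
            np.concatenate([ds.X[i] for i in range(6)], axis=1),
            rec38.data[3])

    def test_non_dividing_segment_length_rejected(self, rec38):
        with pytest.raises(ValueError):
            segment(rec38, np.arange(4), np.zeros(40, int), 7)

    def test_round_trip_serialization(self, rec38, tmp_path):
        labels = np.array([0, 1] * 20)
        ds = segment(rec38, np.arange(6), labels, 10)
        save_segments(ds, tmp_path, "t")
        back = load_segments(tmp_path, "t")
        np.testing.assert_array_equal(back.X, ds.X)
        np.testing.assert_array_equal(back.y, ds.y)
        assert back.montage.names == ds.montage.names


class TestSplit:
    def test_1140_balanced_splits_570_285_285(self):
        y = np.repeat([0, 1], 570)
        trial_of = np.repeat(np.arange(38), 30)
        tr, va, te = split_indices(y, trial_of, SplitSpec(seed=0))
        assert (len(tr), len(va), len(te)) == (570, 285, 285)

    def test_partition_disjoint_and_exhaustive(self):
        y = np.repeat([0, 1], 60)
        trial_of = np.repeat(np.arange(12), 10)
        parts = split_indices(y, trial_of, SplitSpec(seed=4))
        allidx = np.concatenate(parts)
        assert len(allidx) == len(y)
        assert len(np.unique(allidx)) == len(y)

    def test_stratified_within_one_instance(self):
        y = np.repeat([0, 1], 60)
        trial_of = np.arange(120)
        for part, frac in zip(split_indices(y, trial_of, SplitSpec(seed=1)),
                              (0.5, 0.25, 0.25)):
            counts = np.bincount(y[part], minlength=2)
            assert abs(counts[0] - counts[1]) <= 1
            assert abs(len(part) - frac * 120) <= 1

    def test_same_seed_identical(self):
        y = np.repeat([0, 1], 50)
        trial_of = np.arange(100)
        a = split_indices(y, trial_of, SplitSpec(seed=9))
        b = split_indices(y, trial_of, SplitSpec(seed=9))
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa, pb)

    def test_trial_grouping_never_splits_a_trial(self):
        y = np.repeat([0, 1], 60)
        trial_of = np.repeat(np.arange(12), 10)
        parts = split_indices(y, trial_of, SplitSpec(seed=2, grouping="trial"))
        seen = [set(trial_of[p]) for p in parts]
        assert not (seen[0] & seen[1] or seen[0] & seen[2] or seen[1] & seen[2])


class TestAdjustKfold:
    @pytest.mark.parametrize("n,k,expected", [(38, 10, 10), (8, 10, 8), (2, 10, 2)])
    def test_k_never_exceeds_n(self, n, k, expected):
        assert adjust_kfold(n, k) == expected

    def test_too_few_instances_rejected(self):
        with pytest.raises(ValueError):
            adjust_kfold(1)
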