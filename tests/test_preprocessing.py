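"""Preprocessing chain: filtering, bad-channel screening, reference, epoching."""

import numpy as np
import pytest
from scipy import signal as sps

from neurocoh.exceptions import ConfigurationError, DataError
from neurocoh.preprocessing import (
    PreprocessConfig,
    bandpass_filter,
    detect_bad_channels,
    preprocess_recording,
    rereference_average,
    segment_conditions,
)

from conftest import make_recording, toy_montage  # noqa: F401


def sine_recording(freq, fs=250.0, seconds=20.0, n_ch=3):
    t = np.arange(int(seconds * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return make_recording(data, fs=fs)


def filter_gain_oracle(freq, cfg=PreprocessConfig(), fs=250.0):
    """|H(f)|^2 of the forward-backward Butterworth band-pass."""
    sos = sps.butter(cfg.filter_order, [cfg.highpass, cfg.lowpass],
                     btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq], fs=fs)
    return float(np.abs(h[0]) ** 2)


class TestBandpass:
    @pytest.mark.parametrize("freq,passes", [(50.0, False), (10.0, True)])
    def test_stopband_and_passband_rms(self, freq, passes):
        rec = sine_recording(freq)
        out = bandpass_filter(rec, PreprocessConfig())
        # steady-state response: exclude 2 s of filter edge transient per end
        sl = slice(500, -500)
        ratio = np.sqrt(np.mean(out.data[:, sl] ** 2) / np.mean(rec.data[:, sl] ** 2))
        oracle = filter_gain_oracle(freq)  # forward-backward gain = |H|^2
        if passes:
            assert ratio > 0.95
        else:
            assert ratio < 0.05
        assert ratio == pytest.approx(oracle, abs=0.02)

    def test_zero_in_zero_out_and_shape(self):
        rec = make_recording(np.zeros((4, 5000)))
        out = bandpass_filter(rec, PreprocessConfig())
        assert np.allclose(out.data, 0.0)
        assert out.data.shape == rec.data.shape
        assert out.annotations == rec.annotations

    def test_too_short_recording_raises(self):
        rec = make_recording(np.zeros((2, 20)), annotations=[("EO", 0, 20)])
        with pytest.raises(DataError):
            bandpass_filter(rec, PreprocessConfig())

    def test_bad_band_rejected(self):
        rec = make_recording(np.zeros((2, 5000)))
        with pytest.raises(ConfigurationError):
            bandpass_filter(rec, PreprocessConfig(highpass=40.0, lowpass=35.0))


class TestBadChannels:
    def test_clean_gaussian_channels_pass(self, rng):
        rec = make_recording(rng.standard_normal((32, 20000)))
        assert detect_bad_channels(rec, PreprocessConfig()) == []

    def test_sparse_spike_channel_flagged(self, rng):
        data = rng.standard_normal((32, 20000))
        spikes = rng.choice(20000, size=100, replace=False)  # 0.5 % of samples
        data[7, spikes] += 20.0
        rec = make_recording(data)
        assert detect_bad_channels(rec, PreprocessConfig()) == ["ch07"]

    def test_identical_channels_none_rejected(self, rng):
        row = rng.standard_normal(5000)
        rec = make_recording(np.tile(row, (5, 1)))
        assert detect_bad_channels(rec, PreprocessConfig()) == []

    def test_permutation_equivariance(self, rng):
        data = rng.standard_normal((16, 10000))
        spikes = rng.choice(10000, size=60, replace=False)
        data[3, spikes] += 25.0
        rec = make_recording(data)
        bad = detect_bad_channels(rec, PreprocessConfig())
        perm = rng.permutation(16)
        montage = toy_montage(16)
        rec_p = make_recording(data[perm])
        # relabel: channel k of rec_p is original channel perm[k]
        bad_p = detect_bad_channels(rec_p, PreprocessConfig())
        orig_of = {f"ch{k:02d}": f"ch{perm[k]:02d}" for k in range(16)}
        assert sorted(orig_of[b] for b in bad_p) == sorted(bad)

    def test_too_few_channels_raise(self, rng):
        rec = make_recording(rng.standard_normal((2, 5000)))
        with pytest.raises(DataError):
            detect_bad_channels(rec, PreprocessConfig())


class TestAverageReference:
    def test_channel_mean_is_zero(self, rng):
        rec = make_recording(rng.standard_normal((8, 4000)) + 3.0)
        out = rereference_average(rec)
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-12)

    def test_idempotent(self, rng):
        rec = make_recording(rng.standard_normal((8, 4000)))
        once = rereference_average(rec)
        twice = rereference_average(once)
        assert np.allclose(once.data, twice.data)

    def test_antisymmetric_pair_unchanged(self, rng):
        x = rng.standard_normal(4000)
        rec = make_recording(np.stack([x, -x]))
        out = rereference_average(rec)
        assert np.allclose(out.data, rec.data)

    def test_commutes_with_filtering(self, rng):
        rec = make_recording(rng.standard_normal((6, 8000)))
        cfg = PreprocessConfig()
        a = rereference_average(bandpass_filter(rec, cfg))
        b = bandpass_filter(rereference_average(rec), cfg)
        assert np.allclose(a.data, b.data, atol=1e-9)


class TestSegmentation:
    def test_three_minute_blocks_yield_56s_epochs(self, rng):
        fs = 250.0
        data = rng.standard_normal((4, int(6 * 60 * fs)))
        ann = []
        for b in range(6):
            ann.append(("EO" if b % 2 == 0 else "EC", b * 15000, (b + 1) * 15000))
        rec = make_recording(data, fs=fs, annotations=ann)
        eo, ec = segment_conditions(rec, PreprocessConfig())
        assert len(eo.epochs) == 3 and len(ec.epochs) == 3
        assert all(e.shape == (4, 14000) for e in eo.epochs + ec.epochs)

    def test_zero_discard_keeps_full_interval(self, rng):
        rec = make_recording(rng.standard_normal((2, 6000)),
                             annotations=[("EO", 0, 3000), ("EC", 3000, 6000)])
        cfg = PreprocessConfig(discard_lead_s=0.0, epoch_s=12.0)
        eo, ec = segment_conditions(rec, cfg)
        assert eo.epochs[0].shape[1] == 3000

    def test_short_remainder_kept_with_warning(self, rng, caplog):
        # 10-s interval, 4-s discard, 56-s target -> one 6-s epoch
        fs = 250.0
        rec = make_recording(rng.standard_normal((2, 2500)), fs=fs,
                             annotations=[("EO", 0, 2500)])
        with caplog.at_level("WARNING"):
            eo, ec = segment_conditions(rec, PreprocessConfig())
        assert len(eo.epochs) == 1
        assert eo.epochs[0].shape[1] == 1500
        assert ec.epochs == []
        assert any("shorter than epoch_s" in r.message for r in caplog.records)

    def test_sample_conservation(self, rng):
        fs = 250.0
        rec = make_recording(rng.standard_normal((2, 45000)), fs=fs,
                             annotations=[("EO", 0, 15000), ("EC", 15000, 30000),
                                          ("EO", 30000, 45000)])
        cfg = PreprocessConfig(discard_lead_s=4.0, epoch_s=600.0)  # no truncation
        eo, ec = segment_conditions(rec, cfg)
        total = sum(e.shape[1] for e in eo.epochs + ec.epochs)
        assert total == 45000 - 3 * 1000

    def test_missing_annotations_raise(self, rng):
        rec = make_recording(rng.standard_normal((2, 5000)), annotations=[])
        with pytest.raises(DataError):
            segment_conditions(rec, PreprocessConfig())

    def test_interval_shorter_than_discard_raises(self, rng):
        rec = make_recording(np.zeros((2, 500)), annotations=[("EO", 0, 500)])
        with pytest.raises(DataError):
            segment_conditions(rec, PreprocessConfig(discard_lead_s=4.0))

    def test_rejected_channels_excluded(self, rng):
        rec = make_recording(rng.standard_normal((4, 5000)))
        eo, _ = segment_conditions(rec, PreprocessConfig(discard_lead_s=0.0, epoch_s=10.0),
                                   rejected_channels=["ch01"])
        assert eo.montage.labels == ("ch00", "ch02", "ch03")
        assert all(e.shape[0] == 3 for e in eo.epochs)


class TestFullChain:
    def test_bad_channel_dropped_end_to_end(self, rng):
        # cross-channel z-scores are bounded by sqrt(n-1), so a threshold of 5
        # needs a few dozen channels to be able to fire at all
        data = rng.standard_normal((32, 30000))
        spikes = rng.choice(30000, size=150, replace=False)
        data[2, spikes] += 30.0
        rec = make_recording(data, annotations=[("EO", 0, 15000), ("EC", 15000, 30000)])
        cfg = PreprocessConfig(discard_lead_s=2.0, epoch_s=50.0)
        eo, ec = preprocess_recording(rec, cfg)
        assert "ch02" in eo.rejected_channels
        assert "ch02" not in eo.montage.labels
        assert eo.epochs[0].shape[0] == 31

    def test_cleaning_hook_applied(self, rng):
        rec = make_recording(rng.standard_normal((4, 20000)))
        scale = lambda r: r.copy_with(data=r.data * 2.0)  # noqa: E731
        eo_plain, _ = preprocess_recording(rec)
        eo_hook, _ = preprocess_recording(rec, cleaning_hook=scale)
        assert np.allclose(eo_hook.epochs[0], 2.0 * eo_plain.epochs[0])
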