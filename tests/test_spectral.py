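"""Spectral chain: notch, re-referencing, epoching, Morlet power, gamma traces."""

import numpy as np
import pytest

from ieegcontrast.geometry import Contact
from ieegcontrast.spectral import (EpochSet, SpectralConfig, baseline_correct,
                                   common_average_reference, epoch_and_resample,
                                   gamma_trace, gpt_pipeline, gpt_time_axis,
                                   morlet_power, notch_filter)

FS = 1024.0


def sine(freq, fs=FS, seconds=10.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestNotchFilter:
    def test_line_frequency_strongly_attenuated(self):
        x = sine(50.0)[None, :]
        y = notch_filter(x, FS)
        core = slice(1024, -1024)  # ignore filter edges
        assert np.sqrt((y[0, core] ** 2).mean()) < 0.05 * np.sqrt((x[0, core] ** 2).mean())

    def test_passband_untouched(self):
        x = sine(20.0)[None, :]
        y = notch_filter(x, FS)
        core = slice(1024, -1024)
        ratio = np.sqrt((y[0, core] ** 2).mean()) / np.sqrt((x[0, core] ** 2).mean())
        assert abs(ratio - 1.0) < 0.02

    def test_zeros_in_zeros_out(self):
        x = np.zeros((2, 4096))
        assert np.allclose(notch_filter(x, FS), 0.0)

    def test_rejects_low_sampling_rate(self):
        with pytest.raises(ValueError):
            notch_filter(np.zeros((1, 1000)), fs=250.0)


class TestCommonAverageReference:
    def test_identical_channels_cancel(self):
        x = np.tile(sine(7.0, seconds=1.0), (2, 1))
        assert np.allclose(common_average_reference(x), 0.0)

    def test_zero_mean_pair_unchanged(self):
        x = np.vstack([np.ones(100), -np.ones(100)])
        assert np.allclose(common_average_reference(x), x)

    def test_bad_channel_referenced_but_not_contributing(self):
        # 4 channels x 3 samples, channel 3 marked bad
        x = np.array([[1.0, 2.0, 3.0],
                      [3.0, 2.0, 1.0],
                      [2.0, 2.0, 2.0],
                      [100.0, 100.0, 100.0]])
        good = np.array([True, True, True, False])
        ref = x[:3].mean(axis=0)  # (2, 2, 2)
        out = common_average_reference(x, good)
        assert np.allclose(out, x - ref)

    def test_good_channel_mean_is_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 500))
        good = np.array([True, True, True, True, False, False])
        out = common_average_reference(x, good)
        assert np.max(np.abs(out[good].mean(axis=0))) < 1e-9 * x.std()

    def test_needs_two_good_channels(self):
        with pytest.raises(ValueError):
            common_average_reference(np.zeros((3, 10)), np.array([True, False, False]))


class TestEpochAndResample:
    def test_empty_onsets(self):
        epochs = epoch_and_resample(np.zeros((1, 10000)), FS, [])
        assert epochs.n_trials == 0

    def test_buffered_epoch_sample_count(self):
        # [-0.3-1, 1+1] s window resampled to 256 Hz -> round(3.3 * 256) samples
        fs = 4096.0
        x = np.zeros((1, int(8 * fs)))
        epochs = epoch_and_resample(x, fs, [4.0])
        assert epochs.data.shape == (1, 1, int(np.ceil(3.3 * 256)))

    def test_constant_signal_stays_constant(self):
        x = np.full((1, int(8 * FS)), 5.0)
        epochs = epoch_and_resample(x, FS, [4.0])
        core = epochs.data[0, 0, 50:-50]  # resampler edge ringing excluded
        assert np.allclose(core, 5.0, atol=1e-6)

    def test_edge_onset_dropped_with_warning(self):
        x = np.zeros((1, int(4 * FS)))
        with pytest.warns(UserWarning, match="dropped"):
            epochs = epoch_and_resample(x, FS, [0.5, 2.0], conditions=["angry", "happy"])
        assert epochs.n_trials == 1
        assert list(epochs.conditions) == ["happy"]


def buffered_epochs(signal_fn, n_trials=1, n_channels=1, fs=FS):
    x = np.stack([signal_fn(ch) for ch in range(n_channels)])
    onsets = [4.0 + 6.0 * k for k in range(n_trials)]
    duration = onsets[-1] + 4.0
    assert x.shape[1] >= duration * fs
    return epoch_and_resample(x, fs, onsets)


class TestMorletPower:
    def test_pure_tone_peaks_at_its_frequency(self):
        epochs = buffered_epochs(lambda ch: sine(70.0, seconds=10.0))
        power, times, freqs = morlet_power(epochs)
        mid = (times > 0.1) & (times < 0.9)
        profile = power[0, 0][:, mid].mean(axis=1)
        assert freqs[np.argmax(profile)] == pytest.approx(70.0, abs=1.0)

    def test_power_scales_quadratically_with_amplitude(self):
        epochs1 = buffered_epochs(lambda ch: sine(40.0, seconds=10.0))
        epochs3 = buffered_epochs(lambda ch: sine(40.0, seconds=10.0, amp=3.0))
        p1, *_ = morlet_power(epochs1)
        p3, *_ = morlet_power(epochs3)
        assert np.allclose(p3, 9.0 * p1, rtol=1e-6)

    def test_cropped_output_is_finite_on_noise(self):
        rng = np.random.default_rng(1)
        epochs = buffered_epochs(lambda ch: rng.normal(size=int(10 * FS)))
        power, times, _ = morlet_power(epochs)
        assert np.all(np.isfinite(power))
        assert times[0] == pytest.approx(-0.3, abs=1e-9)
        assert times[-1] < 1.0

    def test_rejects_frequency_above_nyquist(self):
        epochs = EpochSet(np.zeros((1, 1, 845)), fs=200.0, t0=-1.3, channel_ids=["a"])
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_power(epochs)


class TestBaselineCorrect:
    def test_constant_power_maps_to_zero_db(self):
        times = gpt_time_axis()
        power = np.full((2, 1, 3, len(times)), 4.2)
        assert np.allclose(baseline_correct(power, times), 0.0)

    def test_doubling_is_three_db(self):
        times = gpt_time_axis()
        power = np.ones((1, 1, 1, len(times)))
        power[..., times >= 0] = 2.0
        out = baseline_correct(power, times)
        assert np.allclose(out[..., times >= 0.1], 10 * np.log10(2), atol=1e-9)

    def test_baseline_window_outside_axis_rejected(self):
        times = gpt_time_axis()
        with pytest.raises(ValueError):
            baseline_correct(np.ones((1, 1, 1, len(times))), times, (-2.0, -1.5))

    def test_zero_baseline_identified(self):
        times = gpt_time_axis()
        power = np.ones((2, 1, 1, len(times)))
        power[1] = 0.0
        with pytest.raises(ValueError, match="\\(1, 0, 0\\)"):
            baseline_correct(power, times)


class TestGammaTrace:
    def test_frequency_constant_power_equals_any_row(self):
        freqs = np.arange(1, 126.0)
        power = np.tile(np.linspace(1, 2, 50), (2, 3, len(freqs), 1))
        trace = gamma_trace(power, freqs)
        assert np.allclose(trace, power[:, :, 0, :])

    def test_band_width_on_unit_grid(self):
        # [55, 115] Hz inclusive on a 1 Hz grid -> 61 rows averaged
        freqs = np.arange(1, 126.0)
        power = np.zeros((1, 1, len(freqs), 4))
        band = (freqs >= 55) & (freqs <= 115)
        assert band.sum() == 61
        power[0, 0, band, :] = 61.0
        assert np.allclose(gamma_trace(power, freqs), 61.0)

    def test_three_frequency_toy_mean(self):
        freqs = np.array([60.0, 80.0, 100.0])
        power = np.arange(12.0).reshape(1, 1, 3, 4)
        assert np.allclose(gamma_trace(power, freqs), power.mean(axis=2))

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            gamma_trace(np.ones((1, 1, 3, 4)), np.array([1.0, 2.0, 3.0]))


class TestEndToEnd:
    def test_burst_recovered_on_injected_channel_only(self):
        """A 70 Hz burst at 0.3-0.5 s must surface in that channel's GPT window."""
        fs = 1024.0
        rng = np.random.default_rng(7)
        n_trials, iti = 6, 6.0
        onsets = 4.0 + iti * np.arange(n_trials)
        n = int((onsets[-1] + 4.0) * fs)
        t = np.arange(n) / fs
        # several channels so the common average barely dilutes the burst
        x = rng.normal(size=(5, n))
        for onset in onsets:
            window = (t >= onset + 0.3) & (t <= onset + 0.5)
            x[0, window] += 3.0 * np.sin(2 * np.pi * 70.0 * t[window])
        contacts = [Contact(f"c{i + 1}", "S1", (8.0 * i, 0, 0), "fusiform", "LH")
                    for i in range(5)]
        gpts = gpt_pipeline(x, fs, onsets, ["angry"] * n_trials, contacts)
        mean0 = gpts[("S1", "c1")].values.mean(axis=0)
        others = np.stack([gpts[("S1", f"c{i + 1}")].values.mean(axis=0) for i in range(1, 5)])
        tax = gpts[("S1", "c1")].times
        peak_t = tax[np.argmax(mean0)]
        assert 0.25 <= peak_t <= 0.55
        in_win = (tax >= 0.3) & (tax <= 0.5)
        assert mean0[in_win].mean() > others[:, in_win].mean(axis=1).max() + 3.0  # dB separation

    def test_gpt_shape_conservation(self):
        fs = 1024.0
        x = np.random.default_rng(0).normal(size=(2, int(12 * fs)))
        contacts = [Contact("c1", "S1", (0, 0, 0), "fusiform", "LH"),
                    Contact("c2", "S1", (5, 0, 0), "fusiform", "LH")]
        gpts = gpt_pipeline(x, fs, [4.0, 8.0], ["angry", "happy"], contacts)
        g = gpts[("S1", "c1")]
        assert g.values.shape == (2, len(gpt_time_axis()))
        assert np.allclose(np.diff(g.times), 1 / 256)
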