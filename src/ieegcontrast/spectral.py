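"""From raw multichannel voltage to per-contact gamma power traces (GPTs).

The preprocessing chain is: FIR notch at 50/100/150 Hz -> common average
reference over the good channels -> epoching on [-0.3, 1] s around stimulus
onset with 1 s buffers on both edges -> resampling to 256 Hz -> Morlet
time-frequency decomposition over 1..125 Hz -> crop back to [-0.3, 1] s ->
baseline correction (dB relative to the pre-stimulus mean) -> average over
the 55-115 Hz band. The resulting gamma power traces, one [trials x time]
matrix per contact, are the common input of all downstream contrast methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
from scipy.signal import resample_poly

import mne

from .geometry import Contact

mne.set_log_level("ERROR")


def default_n_cycles(freqs: np.ndarray) -> np.ndarray:
    """Wavelet cycles per frequency: max(3, f/2), capped at 2f.

    Above 6 Hz the count grows linearly so temporal resolution stays roughly
    constant; lower frequencies keep 3 cycles for a stable estimate. The 2f
    cap (binding only below 1.5 Hz) keeps the slowest wavelets shorter than
    the buffered 3.3 s epoch.
    """
    freqs = np.asarray(freqs, float)
    return np.minimum(np.maximum(3.0, freqs / 2.0), 2.0 * freqs)


@dataclass
class SpectralConfig:
    notch_base_hz: float = 50.0
    notch_harmonics_hz: tuple[float, ...] = (100.0, 150.0)
    notch_width_hz: float = 2.0
    freq_range_hz: tuple[float, float] = (1.0, 125.0)
    freq_step_hz: float = 1.0
    n_cycles_rule: Callable[[np.ndarray], np.ndarray] = default_n_cycles
    gamma_band_hz: tuple[float, float] = (55.0, 115.0)
    target_fs: float = 256.0
    epoch_window_s: tuple[float, float] = (-0.3, 1.0)
    buffer_s: float = 1.0
    baseline_window_s: tuple[float, float] = (-0.3, 0.0)

    @property
    def notch_freqs(self) -> tuple[float, ...]:
        return (self.notch_base_hz, *self.notch_harmonics_hz)

    @property
    def freqs(self) -> np.ndarray:
        lo, hi = self.freq_range_hz
        return np.arange(lo, hi + 0.5 * self.freq_step_hz, self.freq_step_hz)

    def __post_init__(self) -> None:
        lo, hi = self.gamma_band_hz
        flo, fhi = self.freq_range_hz
        if not (flo <= lo <= hi <= fhi):
            raise ValueError("gamma band must lie inside the analysis frequency range")
        if self.target_fs < 2 * fhi:
            raise ValueError("target sampling rate violates Nyquist for the top analysis frequency")


@dataclass
class EpochSet:
    """Epoched multichannel data, [trials x channels x samples]."""

    data: np.ndarray
    fs: float
    t0: float
    channel_ids: list[str]
    conditions: np.ndarray | None = None
    good_channel_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be [trials x channels x samples]")
        if self.conditions is not None and len(self.conditions) != self.data.shape[0]:
            raise ValueError("one condition label per trial required")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.data.shape[2]) / self.fs

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class GammaPowerTraces:
    """Per-contact gamma-band power, [trials x timepoints], baseline-corrected dB."""

    values: np.ndarray
    times: np.ndarray
    contact: Contact
    conditions: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        self.times = np.asarray(self.times, float)
        self.conditions = np.asarray(self.conditions)
        if self.values.ndim != 2:
            raise ValueError("gamma power traces must be [trials x timepoints]")
        if self.values.shape != (len(self.conditions), len(self.times)):
            raise ValueError("trace shape inconsistent with conditions/time axis")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("gamma power traces contain non-finite values")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("time axis must be strictly increasing")

    def split_conditions(self, a: str = "angry", b: str = "happy") -> tuple[np.ndarray, np.ndarray]:
        return self.values[self.conditions == a], self.values[self.conditions == b]


def gpt_time_axis(config: SpectralConfig | None = None) -> np.ndarray:
    """Canonical GPT time axis: [-0.3, 1) s sampled at 256 Hz (333 points)."""
    config = config or SpectralConfig()
    t0, t1 = config.epoch_window_s
    n = int(round((t1 - t0) * config.target_fs))
    return t0 + np.arange(n) / config.target_fs


def notch_filter(signal: np.ndarray, fs: float, config: SpectralConfig | None = None) -> np.ndarray:
    """Zero-phase Hamming-window FIR notch at the line frequency and harmonics."""
    config = config or SpectralConfig()
    if fs <= 2 * max(config.notch_freqs):
        raise ValueError(f"sampling rate {fs} Hz too low to notch at {max(config.notch_freqs)} Hz")
    x = np.atleast_2d(np.asarray(signal, float))
    out = mne.filter.notch_filter(
        x,
        Fs=fs,
        freqs=np.array(config.notch_freqs),
        notch_widths=config.notch_width_hz,
        method="fir",
        fir_window="hamming",
        phase="zero",
        verbose="ERROR",
    )
    return out.reshape(np.shape(signal))


def common_average_reference(signal: np.ndarray, good_channel_mask: np.ndarray | None = None) -> np.ndarray:
    """Subtract the instantaneous mean of the good channels from every channel.

    Bad channels are re-referenced too but never contribute to the reference.
    """
    x = np.asarray(signal, float)
    if x.ndim != 2:
        raise ValueError("expected [channels x samples]")
    mask = np.ones(x.shape[0], bool) if good_channel_mask is None else np.asarray(good_channel_mask, bool)
    if mask.sum() < 2:
        raise ValueError("common average reference needs at least 2 good channels")
    return x - x[mask].mean(axis=0, keepdims=True)


def epoch_and_resample(
    continuous: np.ndarray,
    fs: float,
    onsets_s: Sequence[float],
    config: SpectralConfig | None = None,
    channel_ids: Sequence[str] | None = None,
    conditions: Sequence[str] | None = None,
) -> EpochSet:
    """Cut buffered epochs around stimulus onsets and resample to 256 Hz.

    Each epoch spans [-0.3 - buffer, 1 + buffer] s around its onset; the
    buffer absorbs wavelet edge artifacts and is cropped after the
    time-frequency transform. Onsets too close to a recording edge are
    dropped with a warning.
    """
    config = config or SpectralConfig()
    x = np.atleast_2d(np.asarray(continuous, float))
    t_lo = config.epoch_window_s[0] - config.buffer_s
    t_hi = config.epoch_window_s[1] + config.buffer_s
    n_native = int(round((t_hi - t_lo) * fs))
    ratio = Fraction(int(round(config.target_fs)), int(round(fs)))

    epochs: list[np.ndarray] = []
    kept: list[int] = []
    for k, onset in enumerate(onsets_s):
        start = int(round((onset + t_lo) * fs))
        if start < 0 or start + n_native > x.shape[1]:
            warnings.warn(f"onset {onset:.3f}s too close to the recording edge; trial dropped")
            continue
        epochs.append(x[:, start:start + n_native])
        kept.append(k)

    if epochs:
        stacked = np.stack(epochs)  # [trials x channels x samples]
        data = resample_poly(stacked, ratio.numerator, ratio.denominator, axis=2)
    else:
        data = np.empty((0, x.shape[0], int(np.ceil(n_native * float(ratio)))))
    cond = None if conditions is None else np.asarray(conditions)[kept]
    ids = list(channel_ids) if channel_ids is not None else [f"ch{i}" for i in range(x.shape[0])]
    return EpochSet(data=data, fs=config.target_fs, t0=t_lo, channel_ids=ids, conditions=cond)


def morlet_power(epochs: EpochSet, config: SpectralConfig | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Morlet wavelet power of buffered epochs, cropped to the analysis window.

    Returns ``(power, times, freqs)`` with power shaped
    [trials x channels x freqs x timepoints] on the cropped [-0.3, 1) s axis.
    """
    config = config or SpectralConfig()
    freqs = config.freqs
    if freqs.max() > epochs.fs / 2:
        raise ValueError(f"top analysis frequency {freqs.max()} Hz exceeds Nyquist {epochs.fs / 2} Hz")
    if epochs.n_trials == 0:
        raise ValueError("no epochs to transform")
    power = mne.time_frequency.tfr_array_morlet(
        epochs.data,
        sfreq=epochs.fs,
        freqs=freqs,
        n_cycles=config.n_cycles_rule(freqs),
        output="power",
        zero_mean=True,
        verbose="ERROR",
    )
    times = epochs.times
    t0, t1 = config.epoch_window_s
    keep = (times >= t0 - 1e-9) & (times < t1 - 1e-9)
    return power[..., keep], times[keep], freqs


def baseline_correct(power: np.ndarray, times: np.ndarray, baseline_window_s: tuple[float, float] = (-0.3, 0.0)) -> np.ndarray:
    """dB baseline correction: 10*log10(power / mean power in the baseline window)."""
    b0, b1 = baseline_window_s
    if b0 < times[0] - 1e-9 or b1 > times[-1] + 1e-9:
        raise ValueError(f"baseline window [{b0}, {b1}] outside time axis [{times[0]:.3f}, {times[-1]:.3f}]")
    mask = (times >= b0 - 1e-9) & (times <= b1 + 1e-9)
    base = np.asarray(power, float)[..., mask].mean(axis=-1, keepdims=True)
    if np.any(base <= 0):
        where = tuple(int(v) for v in np.argwhere(base[..., 0] <= 0)[0])
        raise ValueError(f"non-positive baseline mean at index {where} (trial/channel/frequency)")
    return 10.0 * np.log10(power / base)


def gamma_trace(power: np.ndarray, freqs: np.ndarray, gamma_band_hz: tuple[float, float] = (55.0, 115.0)) -> np.ndarray:
    """Average power over the gamma band (inclusive bounds) -> [... x timepoints]."""
    lo, hi = gamma_band_hz
    mask = (freqs >= lo - 1e-9) & (freqs <= hi + 1e-9)
    if not mask.any():
        raise ValueError(f"no analysis frequencies inside the gamma band [{lo}, {hi}] Hz")
    return np.asarray(power, float)[..., mask, :].mean(axis=-2)


def gpt_pipeline(
    continuous: np.ndarray,
    fs: float,
    onsets_s: Sequence[float],
    conditions: Sequence[str],
    contacts: Sequence[Contact],
    config: SpectralConfig | None = None,
    good_channel_mask: np.ndarray | None = None,
) -> dict[tuple[str, str], GammaPowerTraces]:
    """Full chain from continuous voltage to per-contact GammaPowerTraces."""
    config = config or SpectralConfig()
    x = notch_filter(continuous, fs, config)
    x = common_average_reference(x, good_channel_mask)
    epochs = epoch_and_resample(x, fs, onsets_s, config,
                                channel_ids=[c.id for c in contacts], conditions=conditions)
    power, times, freqs = morlet_power(epochs, config)
    power = baseline_correct(power, times, config.baseline_window_s)
    gamma = gamma_trace(power, freqs, config.gamma_band_hz)  # [trials x channels x T]
    return {
        c.key: GammaPowerTraces(values=gamma[:, i], times=times, contact=c, conditions=epochs.conditions)
        for i, c in enumerate(contacts)
    }
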