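"""EEG band power on a 1-s grid: band-pass filtering, STFT, band integration.

Defaults follow standard practice for low-density stress EEG: zero-phase
Butterworth band-pass 0.5-45 Hz of order 4, then a short-time Fourier
transform with a 2-s Hanning taper and 50% overlap (1-s time step, 0.5-Hz
frequency step at 256 Hz), and integration of the power spectral density over
the five canonical bands. Band intervals are half-open [low, high) so each
boundary bin belongs to exactly one band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .series import BANDS, DEFAULT_CHANNELS, BandPowerSeries

__all__ = [
    "EEGRecording",
    "bandpass_eeg",
    "stft_power",
    "integrate_bands",
    "bandpower_from_raw",
]


@dataclass(frozen=True)
class EEGRecording:
    """Uniformly sampled multichannel EEG: samples[channel, sample] in uV."""

    sampling_rate: float
    channels: tuple[str, ...]
    samples: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "channels", tuple(self.channels))
        s = np.asarray(self.samples, float)
        object.__setattr__(self, "samples", s)
        if s.ndim != 2 or s.shape[0] != len(self.channels):
            raise ValueError(
                f"samples must be (n_channels={len(self.channels)}, n_samples), got {s.shape}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate


def bandpass_eeg(
    rec: EEGRecording, low: float = 0.5, high: float = 45.0, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth band-pass, applied per channel.

    Zero-phase (forward-backward) filtering is used so band power carries no
    filter-induced lag that would bias the directional coupling stage.
    """
    nyq = rec.sampling_rate / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high = {high} Hz is at or above Nyquist ({nyq} Hz)")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.sampling_rate, output="sos")
    out = signal.sosfiltfilt(sos, rec.samples, axis=1)
    return EEGRecording(rec.sampling_rate, rec.channels, out, rec.start_time)


@dataclass(frozen=True)
class Spectrogram:
    """Power spectral density per (time, frequency, channel), uV^2/Hz.

    ``times`` are window centres (s, absolute); ``freqs`` in Hz.
    Integrating ``psd * df`` over all frequencies recovers the windowed-signal
    variance (Hanning normalisation included).
    """

    times: np.ndarray
    freqs: np.ndarray
    psd: np.ndarray
    channels: tuple[str, ...]

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def stft_power(
    rec: EEGRecording, window_s: float = 2.0, overlap_frac: float = 0.5
) -> Spectrogram:
    """Short-time Fourier power with a Hanning taper.

    At the defaults (2-s window, 50% overlap, 256 Hz) the spectrogram has a
    frequency bin spacing of exactly 0.5 Hz and a time step of exactly 1 s,
    with frames stamped at window centres.
    """
    fs = rec.sampling_rate
    nper = window_s * fs
    if abs(nper - round(nper)) > 1e-9 or round(nper) < 16:
        raise ValueError("window_s * sampling_rate must be an integer >= 16")
    nper = int(round(nper))
    if rec.samples.shape[1] < nper:
        raise ValueError(
            f"recording ({rec.samples.shape[1]} samples) shorter than one window ({nper})"
        )
    noverlap = int(round(nper * overlap_frac))
    freqs, times, sxx = signal.spectrogram(
        rec.samples,
        fs=fs,
        window=signal.get_window("hann", nper),
        nperseg=nper,
        noverlap=noverlap,
        detrend=False,
        scaling="density",
        mode="psd",
        axis=1,
    )
    # sxx: (channel, freq, time) -> (time, freq, channel)
    psd = np.moveaxis(sxx, [0, 1, 2], [2, 1, 0])
    return Spectrogram(
        times=rec.start_time + times, freqs=freqs, psd=psd, channels=rec.channels
    )


def integrate_bands(
    spec: Spectrogram, band_defs: dict[str, tuple[float, float]] | None = None
) -> BandPowerSeries:
    """Integrate the spectrogram over frequency bands (half-open [low, high)).

    Band power is the sum of ``psd * df`` over bins whose centre frequency
    satisfies low <= f < high; units uV^2.
    """
    band_defs = dict(BANDS) if band_defs is None else dict(band_defs)
    f = spec.freqs
    fmax = f[-1] + spec.df
    power = np.empty((spec.times.size, len(spec.channels), len(band_defs)))
    for b, (name, (low, high)) in enumerate(band_defs.items()):
        if low < f[0] or high > fmax:
            raise ValueError(
                f"band {name} [{low}, {high}) outside spectrogram range [{f[0]}, {fmax})"
            )
        sel = (f >= low - 1e-9) & (f < high - 1e-9)
        power[:, :, b] = spec.psd[:, sel, :].sum(axis=1) * spec.df
    return BandPowerSeries(
        grid=spec.times,
        channels=spec.channels,
        bands=tuple(band_defs),
        power=power,
    )


def bandpower_from_raw(
    rec: EEGRecording,
    *,
    low: float = 0.5,
    high: float = 45.0,
    filter_order: int = 4,
    window_s: float = 2.0,
    overlap_frac: float = 0.5,
    band_defs: dict[str, tuple[float, float]] | None = None,
) -> BandPowerSeries:
    """Filter -> STFT -> band integration, the full raw-EEG-to-band-power chain."""
    filtered = bandpass_eeg(rec, low, high, filter_order)
    return integrate_bands(stft_power(filtered, window_s, overlap_frac), band_defs)
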