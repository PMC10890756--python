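"""Constant-Q auditory filterbank and auditory spectrogram.

The first stage of the STM front end maps a waveform onto a time-frequency
envelope representation resembling the output of the cochlea: a bank of
constant-Q, asymmetric bandpass filters with centre frequencies equally
spaced on a logarithmic axis, followed by envelope extraction in short
analysis windows.

Implementation: the waveform is analysed with a Hann-windowed short-time
Fourier transform (window 40 ms, overlapping hops), and each cochlear
channel's envelope is obtained as a weighted sum of STFT magnitude bins.
The per-channel weight profile is an asymmetric piecewise Gaussian on the
frequency axis whose width is proportional to the centre frequency
(constant Q), with a shallow low-frequency skirt and a steep high-frequency
skirt, floored at the spectral resolution of the 40-ms window.  This is an
envelope detector per channel per window: non-negative, exactly homogeneous
in the input amplitude, and with the constant-Q selectivity the model
requires.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy.signal import get_window, resample_poly

__all__ = ["FilterbankSpec", "AuditorySpectrogram", "auditory_spectrogram"]


@dataclass(frozen=True)
class FilterbankSpec:
    """Parameters of the auditory filterbank and modulation filterbank.

    Parameters
    ----------
    n_channels:
        Number of cochlear channels (default 128).
    span_octaves:
        Logarithmic span covered by the channel centres (default 5.3
        octaves), inclusive of both endpoints.
    base_frequency:
        Centre frequency of the lowest channel in Hz.  110 Hz puts the
        5.3-octave span at ~110-4330 Hz, covering speech f0 and formants.
    window:
        Envelope analysis window in seconds (default 40 ms).
    hop:
        Hop between successive analysis windows in seconds.  The default
        4 ms (250 Hz frame rate) makes the temporal-modulation Nyquist
        125 Hz, comfortably above the highest rate filter.
    scales:
        Spectral modulation filter centres in cycles/octave.
    rate_magnitudes:
        Temporal modulation filter centres in Hz; both signs are applied,
        so the signed-rate axis has twice this many entries.
    sample_rate:
        Internal analysis sample rate; inputs are resampled to this.
    """

    n_channels: int = 128
    span_octaves: float = 5.3
    base_frequency: float = 110.0
    window: float = 0.040
    hop: float = 0.004
    scales: tuple = (0.71, 1.0, 1.41, 2.00, 2.83, 4.00, 5.66, 8.00)
    rate_magnitudes: tuple = (0.25, 0.5, 1.0, 2.0, 4.0, 5.70, 8.0, 11.3, 16.0, 22.6, 32.0)
    sample_rate: int = 16000

    def __post_init__(self):
        if self.n_channels < 2:
            raise ValueError("n_channels must be >= 2")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        scales = np.asarray(self.scales, dtype=float)
        rates = np.asarray(self.rate_magnitudes, dtype=float)
        if scales.size == 0 or np.any(scales <= 0) or np.any(np.diff(scales) <= 0):
            raise ValueError("scales must be positive and strictly increasing")
        if rates.size == 0 or np.any(rates <= 0) or np.any(np.diff(rates) <= 0):
            raise ValueError("rate magnitudes must be positive and strictly increasing")
        if self.window <= 0 or self.hop <= 0:
            raise ValueError("window and hop must be positive")

    # ---- derived geometry -------------------------------------------------

    @property
    def channel_centers(self) -> np.ndarray:
        """Channel centre frequencies in Hz, geometric over `span_octaves`."""
        k = np.arange(self.n_channels)
        return self.base_frequency * 2.0 ** (self.span_octaves * k / (self.n_channels - 1))

    @property
    def channels_per_octave(self) -> float:
        return (self.n_channels - 1) / self.span_octaves

    @property
    def signed_rates(self) -> np.ndarray:
        """Signed rate axis in Hz, ascending; positive = downward sweeps."""
        r = np.asarray(self.rate_magnitudes, dtype=float)
        return np.concatenate([-r[::-1], r])

    @property
    def frame_rate(self) -> float:
        """Spectrogram frame rate in Hz (1 / effective hop)."""
        return self.sample_rate / self.hop_samples

    @property
    def hop_samples(self) -> int:
        return max(1, int(round(self.hop * self.sample_rate)))

    @property
    def window_samples(self) -> int:
        return max(2, int(round(self.window * self.sample_rate)))

    @property
    def n_features(self) -> int:
        """Features per frame: channels x scales x signed rates."""
        return self.n_channels * len(self.scales) * 2 * len(self.rate_magnitudes)

    # ---- filter shapes ----------------------------------------------------

    def _sigmas_hz(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-channel (low-side, high-side) Gaussian widths in Hz.

        Constant-Q: widths proportional to the centre frequency, with the
        high-frequency skirt twice as steep as the low-frequency one
        (cochlear-style asymmetry).  Both are floored at the spectral
        resolution of the analysis window so that low channels remain
        resolvable on the STFT bin grid.
        """
        fc = self.channel_centers
        spacing_oct = self.span_octaves / (self.n_channels - 1)
        floor = 1.0 / self.window  # window-limited resolution, Hz
        sig_low = np.maximum(fc * (2.0 ** spacing_oct - 1.0), floor)
        sig_high = np.maximum(fc * (2.0 ** (spacing_oct / 2.0) - 1.0), floor)
        return sig_low, sig_high

    def channel_gain(self, freq, channel: int) -> np.ndarray:
        """Designed magnitude response of one channel at frequency `freq` (Hz)."""
        fc = self.channel_centers[channel]
        sig_low, sig_high = self._sigmas_hz()
        f = np.asarray(freq, dtype=float)
        d = f - fc
        sig = np.where(d > 0, sig_high[channel], sig_low[channel])
        g = np.exp(-0.5 * (d / sig) ** 2)
        return np.where(f <= 0, 0.0, g)

    def channel_weights(self, freqs: np.ndarray) -> np.ndarray:
        """Weight matrix (n_channels, len(freqs)), rows normalised to sum 1."""
        fc = self.channel_centers[:, None]
        sig_low, sig_high = self._sigmas_hz()
        f = np.asarray(freqs, dtype=float)[None, :]
        d = f - fc
        sig = np.where(d > 0, sig_high[:, None], sig_low[:, None])
        w = np.exp(-0.5 * (d / sig) ** 2)
        w[np.broadcast_to(f <= 0, w.shape)] = 0.0
        w /= w.sum(axis=1, keepdims=True)
        return w


@dataclass
class AuditorySpectrogram:
    """Time-frequency envelope array from the cochlear filterbank.

    `values` has shape (n_windows, n_channels) and is non-negative.
    """

    values: np.ndarray
    frame_rate: float
    channel_centers: np.ndarray
    spec: FilterbankSpec = field(repr=False)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.shape[0]) / self.frame_rate

    @property
    def duration(self) -> float:
        return self.values.shape[0] / self.frame_rate


def _as_mono(waveform: np.ndarray) -> np.ndarray:
    w = np.asarray(waveform, dtype=float)
    if w.ndim == 2:  # stereo or multichannel: average channels
        w = w.mean(axis=1 if w.shape[1] < w.shape[0] else 0)
    if w.ndim != 1:
        raise ValueError("waveform must be 1-D (or 2-D multichannel)")
    return w


def resample_to(waveform: np.ndarray, sample_rate: int, target_rate: int) -> np.ndarray:
    """Polyphase resampling to `target_rate`."""
    if sample_rate == target_rate:
        return np.asarray(waveform, dtype=float)
    frac = Fraction(target_rate, int(round(sample_rate))).limit_denominator(1 << 14)
    return resample_poly(np.asarray(waveform, dtype=float), frac.numerator, frac.denominator)


def auditory_spectrogram(
    waveform: np.ndarray,
    sample_rate: int,
    spec: FilterbankSpec | None = None,
) -> AuditorySpectrogram:
    """Compute the auditory spectrogram of a waveform.

    The waveform is downmixed to mono, resampled to ``spec.sample_rate``
    (16 kHz by default), windowed into overlapping 40-ms Hann windows, and
    each window's magnitude spectrum is mapped onto constant-Q log-spaced
    channels.

    Raises
    ------
    ValueError
        If the waveform is empty or shorter than one analysis window.
    """
    spec = spec or FilterbankSpec()
    w = _as_mono(waveform)
    if w.size == 0:
        raise ValueError("empty waveform")
    if not np.all(np.isfinite(w)):
        raise ValueError("waveform contains non-finite samples")
    w = resample_to(w, sample_rate, spec.sample_rate)

    nwin = spec.window_samples
    nhop = spec.hop_samples
    if w.size < nwin:
        raise ValueError(
            f"waveform shorter than one analysis window ({w.size} < {nwin} samples)"
        )
    n_frames = 1 + (w.size - nwin) // nhop
    idx = np.arange(nwin)[None, :] + nhop * np.arange(n_frames)[:, None]
    frames = w[idx] * get_window("hann", nwin, fftbins=True)[None, :]

    nfft = 1 << max(10, math.ceil(math.log2(nwin)))
    mag = np.abs(np.fft.rfft(frames, n=nfft, axis=1))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / spec.sample_rate)
    weights = spec.channel_weights(freqs)  # (C, bins)
    values = mag @ weights.T  # (T, C), non-negative
    return AuditorySpectrogram(
        values=values,
        frame_rate=spec.sample_rate / nhop,
        channel_centers=spec.channel_centers,
        spec=spec,
    )
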