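"""Spectro-temporal modulation (STM) analysis of auditory spectrograms.

The auditory spectrogram s(t, x) (time x log-frequency) is taken into the
2-D modulation domain with a 2-D Fourier transform.  Its axes there are
temporal modulation frequency omega (Hz, "rate") and spectral modulation
frequency k (cycles/octave, "scale").  For each (rate, scale) filter
centre, the modulation spectrum is weighted by a 2-D Gaussian (separable
and constant-Q on log-spaced centres, adjacent filters crossing at -3 dB),
transformed back, and the magnitude stored.  The result is a 4-D tensor
over (time, frequency channel, scale, signed rate).

Sign convention: a temporal modulation coupled with a DOWNWARD frequency
sweep has its 2-D Fourier mass in the quadrants where sign(omega) equals
sign(k); such components are assigned POSITIVE rates.  Negative rates mark
upward sweeps.  Only the analytic (omega > 0) half-plane is kept before
inverse transforming, so the magnitude is a proper modulation envelope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .filterbank import AuditorySpectrogram, FilterbankSpec

__all__ = [
    "STMTensor",
    "Map2D",
    "stm_transform",
    "stm_frame_features",
    "frame_features",
    "project",
    "relative_difference",
    "modulation_weight_2d",
]

_LN2 = np.log(2.0)


def _log_gaussian_sigmas(centers: np.ndarray) -> np.ndarray:
    """Per-centre Gaussian widths in log2 units.

    Chosen so that adjacent filters on the (possibly non-uniform)
    log-spaced centre grid cross at -3 dB; edge filters reuse their single
    neighbour's spacing.
    """
    lc = np.log2(centers)
    d = np.diff(lc)
    if d.size == 0:  # single filter: half-octave width
        spacing = np.array([0.5])
    else:
        left = np.concatenate([[d[0]], d])
        right = np.concatenate([d, [d[-1]]])
        spacing = 0.5 * (left + right)
    # exp(-(spacing/2)^2 / (2 sigma^2)) = 2^(-1/2)  =>  sigma = spacing / (2 sqrt(ln 2))
    return spacing / (2.0 * np.sqrt(_LN2))


def _axis_weight(freqs_abs: np.ndarray, center: float, sigma_log2: float) -> np.ndarray:
    """Constant-Q Gaussian on the log2 axis; zero at zero frequency."""
    w = np.zeros_like(freqs_abs)
    pos = freqs_abs > 0
    w[pos] = np.exp(-0.5 * ((np.log2(freqs_abs[pos] / center)) / sigma_log2) ** 2)
    return w


def modulation_weight_2d(
    omega: np.ndarray,
    kappa: np.ndarray,
    rate: float,
    scale: float,
    rate_sigma: float,
    scale_sigma: float,
) -> np.ndarray:
    """2-D modulation-domain weight for one signed (rate, scale) filter.

    `omega` (Hz) and `kappa` (cyc/oct) are FFT frequency vectors for the
    time and log-frequency axes.  Only the omega > 0 half-plane is kept
    (analytic signal in time); within it, the quadrant with
    sign(kappa) == sign(rate) is selected.
    """
    w_r = _axis_weight(np.abs(omega), abs(rate), rate_sigma)
    w_r[omega <= 0] = 0.0
    w_s = _axis_weight(np.abs(kappa), scale, scale_sigma)
    sign = 1.0 if rate > 0 else -1.0
    w_s = np.where(np.sign(kappa) == sign, w_s, 0.0)
    # The unpaired Nyquist bin of an even-length axis carries both signs at
    # once; drop it so the up/down quadrants stay exact mirror images.
    if kappa.size % 2 == 0:
        w_s[np.argmin(kappa)] = 0.0
    return np.outer(w_r, w_s)


@dataclass
class STMTensor:
    """4-D spectro-temporal modulation magnitudes.

    `values` has shape (time, frequency, scale, signed rate) and is
    non-negative.  Axis vectors carry physical units.
    """

    values: np.ndarray
    times: np.ndarray  # s
    frequencies: np.ndarray  # Hz
    scales: np.ndarray  # cyc/oct
    rates: np.ndarray  # signed Hz, ascending
    spec: FilterbankSpec = field(repr=False)
    truncated_filters: list = field(default_factory=list)


@dataclass
class Map2D:
    """A labelled 2-D projection of the STM representation."""

    values: np.ndarray
    plane: str  # "rate-scale" or "frequency-rate"
    row_axis: np.ndarray
    col_axis: np.ndarray
    row_label: str = ""
    col_label: str = ""
    undefined_cells: np.ndarray | None = None


def _modulation_axes(n_time: int, n_chan: int, spec: FilterbankSpec):
    omega = np.fft.fftfreq(n_time, d=1.0 / spec.frame_rate)
    kappa = np.fft.fftfreq(n_chan, d=1.0 / spec.channels_per_octave)
    return omega, kappa


def _filter_bank_2d(n_time: int, n_chan: int, spec: FilterbankSpec):
    """Yield (scale index, signed-rate index, 2-D weight array)."""
    omega, kappa = _modulation_axes(n_time, n_chan, spec)
    rate_sig = _log_gaussian_sigmas(np.asarray(spec.rate_magnitudes))
    scale_sig = _log_gaussian_sigmas(np.asarray(spec.scales))
    rates = spec.signed_rates
    nyq_rate = spec.frame_rate / 2.0
    nyq_scale = spec.channels_per_octave / 2.0
    truncated = [("scale", float(s)) for s in spec.scales if s > nyq_scale]
    truncated += [("rate", float(r)) for r in spec.rate_magnitudes if r > nyq_rate]
    if truncated:
        warnings.warn(
            f"modulation filter centres beyond the Nyquist of the modulation "
            f"domain (rate {nyq_rate:g} Hz, scale {nyq_scale:g} cyc/oct) are "
            f"truncated: {truncated}",
            RuntimeWarning,
            stacklevel=3,
        )

    mag_sigma = dict(zip(spec.rate_magnitudes, rate_sig))
    for ri, r in enumerate(rates):
        for si, s in enumerate(spec.scales):
            w = modulation_weight_2d(omega, kappa, r, s, mag_sigma[abs(r)], scale_sig[si])
            yield si, ri, w, truncated


def stm_transform(spec_gram: AuditorySpectrogram, spec: FilterbankSpec | None = None) -> STMTensor:
    """Full 4-D STM tensor of an auditory spectrogram.

    Materialises (time, frequency, scale, rate) in float32; for long
    recordings prefer :func:`stm_frame_features`, which averages frames on
    the fly without holding the tensor.
    """
    spec = spec or spec_gram.spec
    s = np.asarray(spec_gram.values, dtype=float)
    if s.ndim != 2 or s.shape[0] < 2 or s.shape[1] < 2:
        raise ValueError("spectrogram must be at least 2x2")
    n_t, n_c = s.shape
    F = np.fft.fft2(s)
    rates = spec.signed_rates
    out = np.empty((n_t, n_c, len(spec.scales), rates.size), dtype=np.float32)
    truncated: list = []
    for si, ri, w, trunc in _filter_bank_2d(n_t, n_c, spec):
        truncated = trunc
        out[:, :, si, ri] = 2.0 * np.abs(np.fft.ifft2(F * w))
    return STMTensor(
        values=out,
        times=np.arange(n_t) / spec_gram.frame_rate,
        frequencies=spec_gram.channel_centers,
        scales=np.asarray(spec.scales, dtype=float),
        rates=rates,
        spec=spec,
        truncated_filters=truncated,
    )


def stm_frame_features(
    spec_gram: AuditorySpectrogram,
    spec: FilterbankSpec | None = None,
    frame_length: float = 15.0,
) -> np.ndarray:
    """Frame-averaged, flattened STM features.

    The recording is cut into non-overlapping frames of `frame_length`
    seconds aligned to its start (trailing remainder dropped); within each
    frame the STM magnitude is averaged over time and flattened in
    (channel, scale, rate) C-order.  Returns an array of shape
    (n_frames, n_channels * n_scales * n_signed_rates); empty (0, d) with a
    warning when the recording is shorter than one frame.
    """
    spec = spec or spec_gram.spec
    s = np.asarray(spec_gram.values, dtype=float)
    n_t, n_c = s.shape
    per = int(round(frame_length * spec_gram.frame_rate))
    n_frames = n_t // per
    d = spec.n_features
    if n_frames == 0:
        warnings.warn(
            f"recording shorter than one {frame_length:g}-s frame; no features",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.empty((0, d))
    F = np.fft.fft2(s)
    n_scales = len(spec.scales)
    n_rates = spec.signed_rates.size
    out = np.empty((n_frames, n_c, n_scales, n_rates))
    keep = n_frames * per
    for si, ri, w, _ in _filter_bank_2d(n_t, n_c, spec):
        y = 2.0 * np.abs(np.fft.ifft2(F * w))
        out[:, :, si, ri] = y[:keep].reshape(n_frames, per, n_c).mean(axis=1)
    return out.reshape(n_frames, d)


def frame_features(stm: STMTensor, frame_length: float = 15.0) -> np.ndarray:
    """Frame-average a materialised STM tensor (see :func:`stm_frame_features`)."""
    v = stm.values
    frame_rate = 1.0 / (stm.times[1] - stm.times[0]) if stm.times.size > 1 else stm.spec.frame_rate
    per = int(round(frame_length * frame_rate))
    n_frames = v.shape[0] // per
    d = v.shape[1] * v.shape[2] * v.shape[3]
    if n_frames == 0:
        warnings.warn(
            f"recording shorter than one {frame_length:g}-s frame; no features",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.empty((0, d))
    keep = n_frames * per
    avg = v[:keep].reshape(n_frames, per, *v.shape[1:]).astype(float).mean(axis=1)
    return avg.reshape(n_frames, d)


def _to_cube(x, spec: FilterbankSpec) -> np.ndarray:
    """Coerce tensor / frame vector / mask to (channel, scale, rate)."""
    if isinstance(x, STMTensor):
        return np.asarray(x.values, dtype=float).mean(axis=0)
    a = np.asarray(x, dtype=float)
    shape = (spec.n_channels, len(spec.scales), 2 * len(spec.rate_magnitudes))
    if a.ndim == 1:
        if a.size != np.prod(shape):
            raise ValueError(f"vector of length {a.size} does not match spec {shape}")
        return a.reshape(shape)
    if a.ndim == 3:
        return a
    if a.ndim == 4:
        return a.mean(axis=0)
    raise ValueError("cannot interpret input as an STM object")


def project(x, plane: str, spec: FilterbankSpec | None = None) -> Map2D:
    """Project an STM tensor, frame vector or mask onto a named plane.

    ``"rate-scale"`` averages over frequency channels (rows = scale,
    columns = signed rate); ``"frequency-rate"`` averages over scales
    (rows = frequency, columns = signed rate).  Time, when present, is
    always averaged.
    """
    if spec is None:
        spec = x.spec if isinstance(x, STMTensor) else FilterbankSpec()
    cube = _to_cube(x, spec)
    rates = spec.signed_rates
    if plane == "rate-scale":
        return Map2D(
            values=cube.mean(axis=0),
            plane=plane,
            row_axis=np.asarray(spec.scales, dtype=float),
            col_axis=rates,
            row_label="scale (cyc/oct)",
            col_label="rate (Hz)",
        )
    if plane == "frequency-rate":
        return Map2D(
            values=cube.mean(axis=1),
            plane=plane,
            row_axis=spec.channel_centers,
            col_axis=rates,
            row_label="frequency (Hz)",
            col_label="rate (Hz)",
        )
    raise ValueError(f"unknown projection plane {plane!r}")


def relative_difference(a: Map2D, b: Map2D) -> Map2D:
    """Relative before/after difference map, in percent.

    Elementwise ``100 * 2 |B - A| / (A + B)``; ranges from 0 (identical)
    to 200 (all mass in one condition).  Cells where A + B == 0 are set to
    0 and flagged in ``undefined_cells``.
    """
    if a.plane != b.plane or a.values.shape != b.values.shape:
        raise ValueError("maps must share plane and shape")
    av, bv = np.asarray(a.values, float), np.asarray(b.values, float)
    denom = av + bv
    if np.any(denom < 0):
        raise ValueError("relative difference requires non-negative maps")
    undefined = denom == 0
    out = np.zeros_like(denom)
    np.divide(200.0 * np.abs(bv - av), denom, out=out, where=~undefined)
    return Map2D(
        values=out,
        plane=a.plane,
        row_axis=a.row_axis,
        col_axis=a.col_axis,
        row_label=a.row_label,
        col_label=a.col_label,
        undefined_cells=undefined,
    )
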