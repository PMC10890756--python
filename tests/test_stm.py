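"""Modulation-filtering properties: oracle equivalence, localisation,
sign convention, projections and frame averaging."""

import numpy as np
import pytest

from voxstm.filterbank import AuditorySpectrogram, FilterbankSpec
from voxstm.stm import (
    STMTensor,
    frame_features,
    project,
    relative_difference,
    stm_frame_features,
    stm_transform,
)
from voxstm.validation import ripple_localization, stm_bruteforce_error


def _sgram(values, spec, frame_rate=None):
    return AuditorySpectrogram(
        values=values,
        frame_rate=frame_rate or 1.0 / spec.hop,
        channel_centers=spec.channel_centers,
        spec=spec,
    )


def test_matches_bruteforce_dft_oracle():
    """FFT-path filtering equals an explicit-DFT implementation."""
    assert stm_bruteforce_error(seed=0, n_trials=3) < 1e-6


def test_ripple_localization_and_sign_convention():
    """A 4 Hz / 2 cyc/oct downward ripple peaks at (+4 Hz, 2 cyc/oct)."""
    res = ripple_localization()
    assert res["rate_argmax"] == pytest.approx(4.0)
    assert res["scale_argmax"] == pytest.approx(2.0)
    assert res["mirror_rel_error"] < 1e-6


def test_upward_ripple_maps_to_negative_rate():
    spec = FilterbankSpec(
        n_channels=64, hop=0.008,
        scales=(0.71, 1.0, 1.41, 2.0, 2.83, 4.0),
        rate_magnitudes=(0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
    )
    fr = 1.0 / spec.hop
    t = np.arange(256) / fr
    x = np.arange(spec.n_channels) / spec.channels_per_octave
    s = 1.0 + np.cos(2 * np.pi * (4.0 * t[:, None] - 2.0 * x[None, :]))  # upward
    rs = project(stm_transform(_sgram(s, spec), spec), "rate-scale", spec)
    i, j = np.unravel_index(np.argmax(rs.values), rs.values.shape)
    assert rs.col_axis[j] == pytest.approx(-4.0)
    assert rs.row_axis[i] == pytest.approx(2.0)


def test_time_constant_spectrogram_has_no_fast_rate_energy(rng):
    """A spectrogram constant in time carries no temporal modulation."""
    spec = FilterbankSpec(n_channels=24, hop=0.008, scales=(0.71, 2.0),
                          rate_magnitudes=(0.5, 2.0, 8.0))
    pattern = rng.random(24)
    s = np.tile(pattern, (64, 1))
    stm = stm_transform(_sgram(s, spec), spec)
    energy = stm.values.astype(float).sum(axis=(0, 1, 2))
    fast = np.abs(stm.rates) >= 2.0
    assert energy[fast].sum() <= 0.01 * max(energy.sum(), 1e-300) + 1e-12


def test_nyquist_truncation_warns():
    spec = FilterbankSpec(n_channels=8, hop=0.04, scales=(0.71,),
                          rate_magnitudes=(2.0, 32.0))  # 32 Hz > 12.5 Hz Nyquist
    s = np.random.default_rng(0).random((32, 8))
    with pytest.warns(RuntimeWarning, match="Nyquist"):
        stm = stm_transform(_sgram(s, spec), spec)
    assert ("rate", 32.0) in stm.truncated_filters


def test_too_small_spectrogram_raises():
    spec = FilterbankSpec(n_channels=8, scales=(1.0,), rate_magnitudes=(2.0,))
    with pytest.raises(ValueError):
        stm_transform(_sgram(np.ones((1, 8)), spec), spec)


# ---- frame features ------------------------------------------------------


def _toy_tensor(n_time, frame_rate=1.0):
    spec = FilterbankSpec(n_channels=2, scales=(1.0,), rate_magnitudes=(2.0,))
    values = np.ones((n_time, 2, 1, 2), dtype=np.float32)
    return STMTensor(
        values=values,
        times=np.arange(n_time) / frame_rate,
        frequencies=spec.channel_centers,
        scales=np.array([1.0]),
        rates=spec.signed_rates,
        spec=spec,
    )


def test_31_minute_recording_yields_124_frames():
    # 1860 s at 1 window/s -> floor(1860 / 15) = 124 non-overlapping frames
    feats = frame_features(_toy_tensor(1860), frame_length=15.0)
    assert feats.shape == (124, 4)


def test_constant_tensor_frame_equals_pattern():
    stm = _toy_tensor(45)
    stm.values *= 3.25
    feats = frame_features(stm, frame_length=15.0)
    assert np.allclose(feats, 3.25)


def test_recording_shorter_than_frame_warns_and_empty():
    with pytest.warns(RuntimeWarning, match="shorter"):
        feats = frame_features(_toy_tensor(10), frame_length=15.0)
    assert feats.shape == (0, 4)


def test_streaming_frame_features_match_tensor_path(rng):
    spec = FilterbankSpec(n_channels=16, hop=0.02, scales=(0.5, 1.0),
                          rate_magnitudes=(1.0, 4.0))
    s = rng.random((200, 16))
    sg = _sgram(s, spec)
    a = stm_frame_features(sg, spec, frame_length=1.0)
    full = stm_transform(sg, spec)
    b = frame_features(full, frame_length=1.0)
    assert a.shape == b.shape == (4, spec.n_features)
    assert np.allclose(a, b, rtol=1e-5)


def test_feature_count_formula():
    spec = FilterbankSpec(n_channels=16, scales=(0.71, 2.0), rate_magnitudes=(1.0, 4.0, 16.0))
    assert spec.n_features == 16 * 2 * 6


# ---- projections and difference maps -------------------------------------


def test_projection_of_single_cell_tensor():
    spec = FilterbankSpec(n_channels=4, scales=(1.0, 2.0), rate_magnitudes=(1.0, 4.0))
    cube = np.zeros((4, 2, 4))
    cube[2, 1, 3] = 8.0  # (freq 2, scale 2.0, rate +4)
    rs = project(cube, "rate-scale", spec)
    assert rs.values.shape == (2, 4)
    assert np.flatnonzero(rs.values)[0] == np.ravel_multi_index((1, 3), rs.values.shape)
    fr = project(cube, "frequency-rate", spec)
    assert fr.values.shape == (4, 4)
    assert fr.values[2, 3] > 0 and np.count_nonzero(fr.values) == 1


def test_projection_is_linear(rng):
    spec = FilterbankSpec(n_channels=4, scales=(1.0, 2.0), rate_magnitudes=(1.0, 4.0))
    a, b = rng.random((4, 2, 4)), rng.random((4, 2, 4))
    pa = project(a, "rate-scale", spec).values
    pb = project(b, "rate-scale", spec).values
    pab = project(a + b, "rate-scale", spec).values
    assert np.allclose(pab, pa + pb)


def test_unknown_plane_raises():
    spec = FilterbankSpec(n_channels=4, scales=(1.0,), rate_magnitudes=(1.0,))
    with pytest.raises(ValueError, match="plane"):
        project(np.ones((4, 1, 2)), "scale-time", spec)


@pytest.mark.parametrize(
    "a,b,expected",
    [
        (1.0, 1.0, 0.0),  # identical maps
        (1.0, 3.0, 100.0),  # B = 3A -> 2*2A/4A = 100%
        (1.0, 0.0, 200.0),  # maximum of the measure
    ],
)
def test_relative_difference_closed_forms(a, b, expected):
    spec = FilterbankSpec(n_channels=4, scales=(1.0,), rate_magnitudes=(1.0,))
    ma = project(np.full((4, 1, 2), a), "rate-scale", spec)
    mb = project(np.full((4, 1, 2), b), "rate-scale", spec)
    diff = relative_difference(ma, mb)
    assert np.allclose(diff.values, expected)


def test_relative_difference_flags_empty_cells_and_shape_mismatch():
    spec = FilterbankSpec(n_channels=4, scales=(1.0,), rate_magnitudes=(1.0,))
    zero = project(np.zeros((4, 1, 2)), "rate-scale", spec)
    diff = relative_difference(zero, zero)
    assert np.all(diff.values == 0) and diff.undefined_cells.all()
    other = project(np.zeros((4, 1, 4)), "rate-scale",
                    FilterbankSpec(n_channels=4, scales=(1.0,), rate_magnitudes=(1.0, 2.0)))
    with pytest.raises(ValueError):
        relative_difference(zero, other)
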