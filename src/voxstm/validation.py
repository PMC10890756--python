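"""Validation experiments exercising the whole pipeline.

Each function here recomputes, from scratch and at a stated problem size,
one of the package's checkable claims: the front end's dimensionality and
oracle equivalence, ripple localisation, classifier calibration on null
and strong-effect synthetic cohorts, reverse-correlation mask recovery,
interpretation-PCA factor recovery, and the generator's sleepiness link.
They are used both by the test suite and by ``scripts/acceptance.py``.

Problem sizes are demo-scale by design (short sessions, the reduced demo
filterbank, tens of simulated participants) so a full pass runs in
minutes on one core; the methods note states the sizes used.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .classify import evaluate_participants, rau
from .cohort import CohortConfig, make_cohort, participant_profiles
from .features import featurize_cohort
from .filterbank import AuditorySpectrogram, FilterbankSpec
from .interpret import ReverseCorrelator, generate_probes, reverse_correlate
from .maskpca import MaskPCA
from .pipeline import demo_filterbank_spec
from .stm import _filter_bank_2d, project, stm_transform

__all__ = [
    "feature_dimensionality",
    "stm_bruteforce_error",
    "ripple_localization",
    "null_calibration",
    "strong_effect_detection",
    "linear_mask_recovery",
    "planted_mask_localization",
    "interpretation_pca_recovery",
    "sleepiness_link_recovery",
    "rau_checks",
]


def feature_dimensionality(seed: int = 0) -> int:
    """Features per 15-s frame under the default filterbank.

    Synthesises a 16-s utterance and runs it through the default front
    end (128 channels x 8 scales x 22 signed rates -> 22,528).
    """
    from .cohort import VoiceParams, synthesize_utterance
    from .features import STMFeaturizer

    wave = synthesize_utterance(VoiceParams(), duration=16.0, sample_rate=16000, seed=seed)
    feats = STMFeaturizer().transform([(wave, 16000)])
    assert feats.shape[0] == 1
    return int(feats.shape[1])


def stm_bruteforce_error(seed: int = 0, n_trials: int = 3, shape=(48, 24)) -> float:
    """Max relative error of the FFT path vs an explicit-DFT oracle."""
    rng = np.random.default_rng(seed)
    spec = FilterbankSpec(
        n_channels=shape[1], hop=0.008, scales=(0.71, 2.0), rate_magnitudes=(1.0, 4.0, 16.0)
    )
    worst = 0.0
    for _ in range(n_trials):
        S = rng.random(shape)
        T, C = S.shape
        sg = AuditorySpectrogram(S, 1.0 / spec.hop, spec.channel_centers, spec)
        fast = stm_transform(sg, spec).values.astype(float)
        Ft = np.exp(-2j * np.pi * np.outer(np.arange(T), np.arange(T)) / T)
        Fx = np.exp(-2j * np.pi * np.outer(np.arange(C), np.arange(C)) / C)
        F = Ft @ S @ Fx.T
        for si, ri, w, _ in _filter_bank_2d(T, C, spec):
            slow = 2.0 * np.abs(np.conj(Ft).T @ (F * w) @ np.conj(Fx)) / (T * C)
            denom = max(slow.max(), 1e-300)
            worst = max(worst, float(np.abs(fast[:, :, si, ri] - slow).max() / denom))
    return worst


def ripple_localization() -> dict:
    """Rate-scale localisation of a 4 Hz / 2 cyc/oct downward ripple.

    Returns the argmax cell of the rate-scale projection and whether
    time-reversing the spectrogram mirrors the signed-rate axis.
    """
    spec = FilterbankSpec(
        n_channels=64,
        hop=0.008,
        scales=(0.71, 1.0, 1.41, 2.0, 2.83, 4.0),
        rate_magnitudes=(0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
    )
    fr = 1.0 / spec.hop
    t = np.arange(256) / fr
    x = np.arange(spec.n_channels) / spec.channels_per_octave
    s = 1.0 + np.cos(2 * np.pi * (4.0 * t[:, None] + 2.0 * x[None, :]))
    sg = AuditorySpectrogram(s, fr, spec.channel_centers, spec)
    stm = stm_transform(sg, spec)
    rs = project(stm, "rate-scale", spec)
    i, j = np.unravel_index(np.argmax(rs.values), rs.values.shape)

    sg_rev = AuditorySpectrogram(s[::-1].copy(), fr, spec.channel_centers, spec)
    stm_rev = stm_transform(sg_rev, spec)
    mirrored = stm_rev.values[::-1, :, :, ::-1]
    mirror_err = float(np.abs(mirrored - stm.values).max() / stm.values.max())
    return {
        "scale_argmax": float(rs.row_axis[i]),
        "rate_argmax": float(rs.col_axis[j]),
        "mirror_rel_error": mirror_err,
    }


def _calibration_cohort(seed: int, n_participants: int, effect: float, effect_sd: float,
                        session_duration: float = 31.0) -> CohortConfig:
    return CohortConfig(
        n_participants=n_participants,
        session_duration=session_duration,
        prosody_effect=effect,
        prosody_sd=effect_sd,
        timbre_effect=0.0,
        timbre_sd=0.0,
        seed=seed,
    )


def null_calibration(
    seed: int = 0,
    n_participants: int = 100,
    n_repeats: int = 50,
    alpha: float = 0.05,
) -> dict:
    """Participant-level classification on a zero-effect cohort.

    All effect multipliers are 0, so before/after frames are exchangeable
    and every classifier works at chance.  Reports the mean participant
    BAcc and the fraction of per-participant t-tests (split BAccs vs 0.5)
    rejecting at `alpha` — the protocol's type-I behaviour.  31-s sessions
    (two 15-s frames each) keep the run in minutes.
    """
    cfg = _calibration_cohort(seed, n_participants, 0.0, 0.0)
    cohort = make_cohort(cfg)
    X, meta = featurize_cohort(cohort, demo_filterbank_spec())
    evs = evaluate_participants(
        X,
        meta.state.to_numpy(),
        meta.participant_id.to_numpy(),
        n_repeats=n_repeats,
        n_components=12,
        seed=seed,
    )
    means = np.array([e.result.mean for e in evs])
    pvals = np.array([e.result.p_value for e in evs])
    rejected = np.sum(pvals[np.isfinite(pvals)] < alpha)
    return {
        "mean_bacc": float(means.mean()),
        "sd_bacc": float(means.std(ddof=1)),
        "rejection_rate": float(rejected / len(evs)),
        "n_participants": len(evs),
        "n_frames_per_participant": int((meta.participant_id == 1).sum()),
    }


def strong_effect_detection(
    seed: int = 0,
    effect: float = 0.5,
    n_seeds: int = 5,
    n_participants: int = 6,
    n_repeats: int = 20,
) -> dict:
    """Participant-level BAcc when every talker has a strong prosody effect.

    `effect` = 0.5 multiplies the after-deprivation AM depth by 1.5 for
    every participant (no spread); averaged over `n_seeds` cohorts.
    """
    all_means = []
    for k in range(n_seeds):
        cfg = _calibration_cohort(seed + k, n_participants, effect, 0.0,
                                  session_duration=60.0)
        cohort = make_cohort(cfg)
        X, meta = featurize_cohort(cohort, demo_filterbank_spec())
        evs = evaluate_participants(
            X,
            meta.state.to_numpy(),
            meta.participant_id.to_numpy(),
            n_repeats=n_repeats,
            n_components=12,
            seed=seed + k,
        )
        all_means.extend(e.result.mean for e in evs)
    return {"mean_bacc": float(np.mean(all_means)), "n_classifiers": len(all_means)}


def linear_mask_recovery(seed: int = 0, d: int = 30, n_probes: int = 10_000) -> float:
    """Cosine similarity between a linear rule's weights and its mask.

    For a linear decision rule sign(w @ z), the reverse-correlation mask
    converges (up to scale) onto w; checked with Gaussian probes around a
    cloud of random frames.
    """
    rng = np.random.default_rng(seed)
    w = rng.standard_normal(d)
    w /= np.linalg.norm(w)
    frames = rng.standard_normal((100, d)) * 0.1  # small spread around origin
    sd = np.ones(d)
    probes = generate_probes(sd, n_frames=frames.shape[0],
                             probes_per_frame=n_probes // frames.shape[0],
                             amplitude=1.0, seed=seed)

    def decide(z):
        return np.where(z @ w > 0, "after", "before")

    mask, _ = reverse_correlate(decide, frames, probes)
    return float(mask @ w / np.linalg.norm(mask))


def planted_mask_localization(seed: int = 0, n_participants: int = 4) -> dict:
    """End-to-end mask sign and localisation for planted prosody effects.

    Every participant gets a positive prosody effect (+0.5); the
    participant-mean interpretation masks should be positive and carry
    most of their absolute rate-scale mass in the 2-8 Hz rate band.
    Also runs the sign flip: a negative effect must flip the band mean.
    """
    out = {}
    for label, effect in (("positive", 0.5), ("negative", -0.5)):
        cfg = _calibration_cohort(seed, n_participants, effect, 0.0, session_duration=60.0)
        cohort = make_cohort(cfg)
        spec = demo_filterbank_spec()
        X, meta = featurize_cohort(cohort, spec)
        y = meta.state.to_numpy()
        evs = evaluate_participants(
            X, y, meta.participant_id.to_numpy(),
            n_repeats=8, n_components=12, seed=seed, keep_models=True,
        )
        band_means, band_fracs = [], []
        for ev in evs:
            masks = []
            for k, clf in enumerate(ev.models):
                rc = ReverseCorrelator(probes_per_frame=25, random_state=seed + k)
                rc.fit(clf, X[ev.frame_index], y[ev.frame_index])
                masks.append(rc.mask_)
            mean_mask = np.mean(masks, axis=0)
            m = project(mean_mask, "rate-scale", spec)
            band = (np.abs(m.col_axis) >= 2) & (np.abs(m.col_axis) <= 8)
            band_means.append(m.values[:, band].mean())
            band_fracs.append(
                np.abs(m.values[:, band]).sum() / max(np.abs(m.values).sum(), 1e-300)
            )
        out[label] = (float(np.mean(band_means)), float(np.mean(band_fracs)))
    return {
        "band_mean_positive": out["positive"][0],
        "band_mean_negative": out["negative"][0],
        "band_abs_fraction": out["positive"][1],
    }


def interpretation_pca_recovery(seed: int = 0, n_masks: int = 22, n_features: int = 1152) -> dict:
    """Recovery of two orthogonal templates from constructed masks.

    Masks are a_i T1 + b_i T2 + noise with var(a) > var(b) >> var(noise);
    the leading two components must span {T1, T2} (small principal
    angles) in the right variance order, and the idealized grid must use
    exactly 30 points on [-2, 2].
    """
    from scipy.linalg import subspace_angles

    rng = np.random.default_rng(seed)
    T1 = rng.standard_normal(n_features)
    T2 = rng.standard_normal(n_features)
    T2 -= (T2 @ T1) / (T1 @ T1) * T1
    T1 /= np.linalg.norm(T1)
    T2 /= np.linalg.norm(T2)
    a = rng.normal(0, 3.0, n_masks)
    b = rng.normal(0, 2.0, n_masks)
    # "var(noise) much smaller than the factor variances" must hold for the
    # TOTAL noise variance across features (n_features * sd^2), not per
    # feature; 0.02 keeps it at ~0.5 against factor variances 9 and 4.
    noise = rng.normal(0, 0.02, (n_masks, n_features))
    M = np.outer(a, T1) + np.outer(b, T2) + noise
    model = MaskPCA(n_components=3).fit(M)
    comps = model.pca_.components_[:2].T
    angles = np.degrees(subspace_angles(comps, np.column_stack([T1, T2])))
    c1 = model.pca_.components_[0]
    c2 = model.pca_.components_[1]
    grid = model.idealized_masks(0)
    return {
        "max_principal_angle_deg": float(np.max(angles)),
        "dim1_matches_T1": bool(abs(c1 @ T1) > abs(c1 @ T2)),
        "dim2_matches_T2": bool(abs(c2 @ T2) > abs(c2 @ T1)),
        "grid_points": int(grid.latent_values.size),
        "grid_min": float(grid.latent_values.min()),
        "grid_max": float(grid.latent_values.max()),
    }


def sleepiness_link_recovery(seed: int = 0, link: float = 0.7, n: int = 200) -> dict:
    """Correlation between planted prosody effects and SSS change.

    Draws participant profiles only (no audio needed) and reports the
    sample correlation at the configured link and at zero link, plus the
    95% sampling CI of r at the planted link.
    """
    prof = participant_profiles(
        CohortConfig(n_participants=n, session_duration=60.0, prosody_sd=0.5,
                     sss_link=link, seed=seed)
    )
    delta = prof.sss_after - prof.sss_before
    r = float(stats.pearsonr(prof.prosody_effect, delta)[0])
    # Fisher CI for the planted link at this n
    z = np.arctanh(link)
    half = 1.96 / np.sqrt(n - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))

    prof0 = participant_profiles(
        CohortConfig(n_participants=n, session_duration=60.0, prosody_sd=0.5,
                     sss_link=0.0, seed=seed + 1)
    )
    delta0 = prof0.sss_after - prof0.sss_before
    r0, p0 = stats.pearsonr(prof0.prosody_effect, delta0)
    return {
        "recovered_r": r,
        "ci_low": ci[0],
        "ci_high": ci[1],
        "null_r": float(r0),
        "null_p": float(p0),
        "n": n,
    }


def rau_checks() -> dict:
    """Closed-form values of the rationalized arcsine transform."""
    return {"rau_0p5": rau(0.5), "rau_1": rau(1.0), "rau_0": rau(0.0)}
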