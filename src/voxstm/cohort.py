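"""Synthetic voice cohort with planted sleep-deprivation effects.

Emulates the study design this package analyses: N participants, each
recorded in three reading sessions before and three after two nights of
sleep restriction, with a Stanford Sleepiness Scale (SSS) self-report per
state.  Because no real recordings ship with the package, a harmonic-plus-
noise voice synthesiser stands in for the undeposited audio.  It is not
intelligible speech; it is engineered so that its energy lives in the
spectro-temporal modulation regions that matter for the analysis:

* a syllabic/prosodic amplitude (and pitch) modulation at a per-talker
  rate drawn from 2-8 Hz  -> temporal modulation ("rate") energy;
* a log-frequency ripple on the spectral envelope, default density near
  2 cyc/oct  -> spectral modulation ("scale") energy typical of vowel
  formant/harmonic structure.

Sleep deprivation is planted as per-participant multiplicative changes of
the two modulation depths in the "after" sessions: `prosody_effect` scales
the 2-8 Hz amplitude-modulation depth and `timbre_effect` scales the
spectral ripple depth.  Effects are multiplicative so their sign maps
directly onto the sign of downstream interpretation masks.  SSS changes
are generated with a configurable correlation (`sss_link`) to the planted
prosody effect.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "VoiceParams",
    "CohortConfig",
    "AudioRecording",
    "Cohort",
    "synthesize_utterance",
    "participant_profiles",
    "make_cohort",
]

_TIMES_OF_DAY = ("09:00", "15:00", "17:00")


@dataclass(frozen=True)
class VoiceParams:
    """Parameters of one synthetic voice."""

    f0: float = 205.0  # fundamental, Hz (all-female cohort)
    f0_contour_rate: float = 4.0  # prosodic modulation rate, Hz (2-8)
    f0_contour_depth: float = 0.02  # relative f0 excursion
    am_depth: float = 0.5  # syllabic amplitude-modulation depth, [0, 1]
    formant_centers: tuple = (500.0, 1500.0, 2500.0)
    formant_gain_db: float = 18.0
    spectral_ripple_density: float = 2.0  # cyc/oct
    spectral_ripple_depth: float = 6.0  # dB peak-to-peak
    spectral_tilt_db_per_oct: float = -4.0
    noise_level: float = 0.01  # additive noise power relative to signal
    # Slow random detuning (Hz, half-range) applied to each harmonic.
    harmonic_detune: float = 0.3
    # Harmonic phases are redrawn every `segment_duration` seconds (with a
    # short equal-power crossfade).  Natural speech is a sequence of
    # quasi-stationary phones; a fully stationary synthesis would give
    # every session a fixed slow-beat structure that acts as a session
    # fingerprint which downstream classifiers exploit.  Independent
    # segments make 15-s frames within a session exchangeable with frames
    # across sessions of the same voice.
    segment_duration: float = 5.0

    def validate(self) -> None:
        if self.f0 <= 0:
            raise ValueError("f0 must be positive")
        if not 0.0 <= self.am_depth <= 1.0:
            raise ValueError("am_depth must lie in [0, 1]")
        if self.spectral_ripple_density <= 0:
            raise ValueError("spectral_ripple_density must be positive")
        if self.f0_contour_rate <= 0:
            raise ValueError("f0_contour_rate must be positive")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    `prosody_effect` / `timbre_effect` are the cohort means of the signed
    per-participant multipliers applied to the corresponding modulation
    depth after deprivation; `prosody_sd` / `timbre_sd` set the
    across-participant spread (the real cohort showed signed effects in
    both directions).  `sss_link` in [-1, 1] is the target correlation
    between a participant's prosody effect and their SSS change.
    """

    n_participants: int = 22
    n_sessions_per_state: int = 3
    session_duration: float = 600.0  # s
    sample_rate: int = 16000
    prosody_effect: float = 0.0
    prosody_sd: float = 0.5
    timbre_effect: float = 0.0
    timbre_sd: float = 0.4
    sss_link: float = 0.7
    sss_shift_mean: float = 1.25  # mean SSS increase after deprivation
    sss_shift_sd: float = 1.0
    session_jitter: float = 0.0  # within-state session-to-session drift
    noise_level: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if self.session_duration <= 15.0:
            raise ValueError("session_duration must exceed 15 s")
        if abs(self.sss_link) > 1.0:
            raise ValueError("|sss_link| must be <= 1")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.n_sessions_per_state < 1:
            raise ValueError("n_sessions_per_state must be >= 1")

    @property
    def n_sessions(self) -> int:
        return 2 * self.n_sessions_per_state


@dataclass
class AudioRecording:
    """One session's waveform plus its metadata."""

    waveform: np.ndarray
    sample_rate: int
    participant_id: int
    session_index: int  # 1..n_sessions; first half "before", second "after"
    state: str  # "before" | "after"
    time_of_day: str
    sss: float


def synthesize_utterance(
    params: VoiceParams,
    duration: float,
    sample_rate: int = 16000,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Harmonic-plus-noise utterance with planted modulation structure.

    A sum of harmonics at ``f0`` (slow pitch contour at the prosodic rate)
    is shaped by a formant-like spectral envelope carrying a log-frequency
    ripple, amplitude-modulated at ``f0_contour_rate`` with depth
    ``am_depth``, plus white noise.  Deterministic for a fixed seed.
    """
    params.validate()
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sample_rate <= 0:
        raise ValueError("sample_rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate

    # Pitch contour: slow sinusoidal excursion at the prosodic rate.
    ph0 = rng.uniform(0, 2 * np.pi)
    f0_t = params.f0 * (
        1.0 + params.f0_contour_depth * np.sin(2 * np.pi * params.f0_contour_rate * t + ph0)
    )
    phase = 2 * np.pi * np.cumsum(f0_t) / sample_rate

    # Voice energy above ~5 kHz is negligible for the 110-4300 Hz analysis
    # span; capping the harmonic stack there keeps synthesis fast.
    f_max = min(0.45 * sample_rate, 5000.0)
    n_harm = max(1, int(f_max / (params.f0 * (1 + params.f0_contour_depth))))
    k = np.arange(1, n_harm + 1)
    fk = k * params.f0

    # Spectral envelope in dB: tilt + formant resonances + log-frequency ripple.
    env_db = params.spectral_tilt_db_per_oct * np.log2(fk / params.f0)
    for fc in params.formant_centers:
        bw = 0.12 * fc + 50.0
        env_db += params.formant_gain_db / (1.0 + ((fk - fc) / bw) ** 2)
    env_db += 0.5 * params.spectral_ripple_depth * np.cos(
        2 * np.pi * params.spectral_ripple_density * np.log2(fk / params.f0)
    )
    amp = 10.0 ** (env_db / 20.0)
    amp /= np.sqrt(np.sum(amp**2))

    wave = np.zeros(n)
    seg_len = max(1, int(round(params.segment_duration * sample_rate)))
    fade = min(int(round(0.1 * sample_rate)), seg_len // 2)
    start = 0
    while start < n:
        stop = min(start + seg_len, n)
        sl = slice(start, min(stop + fade, n))  # extend into the next segment
        harm_phases = rng.uniform(0, 2 * np.pi, size=n_harm)
        detune = rng.uniform(-params.harmonic_detune, params.harmonic_detune, size=n_harm)
        seg = np.zeros(sl.stop - sl.start)
        for i in range(n_harm):  # loop keeps memory at O(n)
            seg += amp[i] * np.sin(
                k[i] * phase[sl] + harm_phases[i] + 2 * np.pi * detune[i] * t[sl]
            )
        # Equal-power crossfade: this segment fades out over [stop, stop+fade)
        # while the next fades in over the same samples.
        env = np.ones_like(seg)
        if start > 0 and fade:
            env[:fade] = np.sqrt(np.linspace(0.0, 1.0, fade))
        if sl.stop < n and fade:
            env[-fade:] = np.sqrt(np.linspace(1.0, 0.0, fade))
        wave[sl] += seg * env
        start = stop

    # Syllabic amplitude modulation, phase-locked to the pitch contour:
    # prosodic pitch and energy rise and fall together.  (A random
    # relative phase would set a session-specific effective modulation
    # depth — a fingerprint unrelated to the planted effects.)
    am = 1.0 + params.am_depth * np.sin(2 * np.pi * params.f0_contour_rate * t + ph0)
    wave *= am / (1.0 + params.am_depth)

    if params.noise_level > 0:
        rms = np.sqrt(np.mean(wave**2))
        wave = wave + rng.standard_normal(n) * np.sqrt(params.noise_level) * rms

    # RMS (not peak) normalisation: the crest factor depends on random
    # phase alignments, so peak scaling would imprint a per-utterance gain.
    rms = np.sqrt(np.mean(wave**2))
    if rms > 0:
        wave *= 0.15 / rms
    return np.clip(wave, -1.0, 1.0)


def participant_profiles(config: CohortConfig) -> pd.DataFrame:
    """Draw per-participant voice traits, planted effects and SSS scores.

    The SSS change after deprivation is ``shift_mean + shift_sd * (link *
    z_p + sqrt(1 - link^2) * eps)`` where ``z_p`` is the participant's
    standardised prosody effect, so that corr(prosody effect, SSS change)
    equals ``sss_link`` in expectation.  Scores are rounded to the quarter
    point (the aggregate of a handful of integer reports) and clipped to
    the 1-7 Stanford range.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC0]))
    n = config.n_participants
    z_p = rng.standard_normal(n)
    z_t = rng.standard_normal(n)
    prosody = config.prosody_effect + config.prosody_sd * z_p
    timbre = config.timbre_effect + config.timbre_sd * z_t

    if config.prosody_sd > 0:
        zp_std = (prosody - prosody.mean()) / prosody.std(ddof=0)
    else:
        zp_std = np.zeros(n)
    eps = rng.standard_normal(n)
    eps = (eps - eps.mean()) / eps.std(ddof=0)
    # Orthogonalise the noise against the planted factor so the realised
    # correlation concentrates tightly on sss_link.
    if config.prosody_sd > 0:
        eps = eps - (eps @ zp_std) / (zp_std @ zp_std) * zp_std
        eps /= max(eps.std(ddof=0), 1e-12)
    link = config.sss_link
    shift = config.sss_shift_mean + config.sss_shift_sd * (
        link * zp_std + np.sqrt(max(0.0, 1.0 - link**2)) * eps
    )
    sss_before = np.clip(rng.normal(2.5, 0.8, size=n), 1.0, 5.0)
    sss_after = np.clip(sss_before + shift, 1.0, 7.0)
    quarter = lambda x: np.round(x * 4) / 4  # noqa: E731  (aggregate of ordinal reports)

    return pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "f0": np.clip(rng.normal(205.0, 18.0, size=n), 150.0, 280.0),
            "am_rate": rng.uniform(2.0, 8.0, size=n),
            "am_depth": rng.uniform(0.4, 0.6, size=n),
            "ripple_depth": rng.uniform(5.0, 8.0, size=n),
            "prosody_effect": prosody,
            "timbre_effect": timbre,
            "sss_before": quarter(sss_before),
            "sss_after": quarter(sss_after),
        }
    )


class Cohort:
    """Lazy container for a synthetic cohort.

    Waveforms are synthesised on demand from (seed, participant, session),
    so the full-duration default cohort never has to sit in memory at
    once.  ``table`` lists one row per recording; ``profiles`` one row per
    participant.
    """

    def __init__(self, config: CohortConfig):
        self.config = config
        self.profiles = participant_profiles(config)
        rows = []
        for _, p in self.profiles.iterrows():
            for s in range(1, config.n_sessions + 1):
                state = "before" if s <= config.n_sessions_per_state else "after"
                rows.append(
                    {
                        "participant_id": int(p.participant_id),
                        "session_index": s,
                        "state": state,
                        "time_of_day": _TIMES_OF_DAY[(s - 1) % len(_TIMES_OF_DAY)],
                        "sss": float(p.sss_before if state == "before" else p.sss_after),
                        "wav_path": "",
                    }
                )
        self.table = pd.DataFrame(rows)

    def __len__(self) -> int:
        return len(self.table)

    def session_params(self, participant_id: int, session_index: int) -> VoiceParams:
        p = self.profiles.set_index("participant_id").loc[participant_id]
        cfg = self.config
        after = session_index > cfg.n_sessions_per_state
        am_depth = float(p.am_depth)
        ripple = float(p.ripple_depth)
        if after:
            am_depth *= 1.0 + float(p.prosody_effect)
            ripple *= 1.0 + float(p.timbre_effect)
        if cfg.session_jitter > 0:
            jr = np.random.default_rng(
                np.random.SeedSequence([cfg.seed, 7, int(participant_id), int(session_index)])
            )
            am_depth *= 1.0 + cfg.session_jitter * jr.standard_normal()
            ripple *= 1.0 + cfg.session_jitter * jr.standard_normal()
        return VoiceParams(
            f0=float(p.f0),
            f0_contour_rate=float(p.am_rate),
            am_depth=float(np.clip(am_depth, 0.0, 1.0)),
            spectral_ripple_depth=float(max(ripple, 0.0)),
            noise_level=cfg.noise_level,
        )

    def recording(self, participant_id: int, session_index: int) -> AudioRecording:
        cfg = self.config
        params = self.session_params(participant_id, session_index)
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, int(participant_id), int(session_index)])
        )
        wave = synthesize_utterance(params, cfg.session_duration, cfg.sample_rate, rng)
        row = self.table[
            (self.table.participant_id == participant_id)
            & (self.table.session_index == session_index)
        ].iloc[0]
        return AudioRecording(
            waveform=wave,
            sample_rate=cfg.sample_rate,
            participant_id=int(participant_id),
            session_index=int(session_index),
            state=str(row.state),
            time_of_day=str(row.time_of_day),
            sss=float(row.sss),
        )

    def recordings(self):
        """Yield every recording, participant-major then session order."""
        for _, row in self.table.iterrows():
            yield self.recording(int(row.participant_id), int(row.session_index))

    def write(self, out_dir, stem: str = "cohort") -> pd.DataFrame:
        """Write one 16-bit PCM WAV per session plus a metadata CSV."""
        from pathlib import Path

        from .io import write_wav

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table = self.table.copy()
        for i, row in table.iterrows():
            rec = self.recording(int(row.participant_id), int(row.session_index))
            path = out / f"p{rec.participant_id:03d}_s{rec.session_index}.wav"
            write_wav(path, rec.waveform, rec.sample_rate)
            table.at[i, "wav_path"] = path.name
        table.to_csv(out / f"{stem}.csv", index=False)
        return table


def make_cohort(config: CohortConfig | None = None, **overrides) -> Cohort:
    """Build a :class:`Cohort` from a config (or keyword overrides)."""
    if config is None:
        config = CohortConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    return Cohort(config)
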