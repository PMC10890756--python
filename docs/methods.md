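# Methods

`voxstm` implements a voice-analysis pipeline for detecting mild sleep
deprivation from speech recordings, built around four ideas: a generic
auditory feature space (spectro-temporal modulations), a standard
classification protocol (PCA + RBF-SVM with balanced-accuracy cross-
validation), a reverse-correlation technique that turns trained
classifiers into interpretable feature maps, and a PCA across those maps
that exposes the main axes of individual variation and their relation to
subjective sleepiness. Because no clinical recordings ship with the
package, a synthetic voice cohort with planted, controllable effects
serves as the test bed; this note states exactly what that cohort does
and does not emulate.

## The STM front end

**Auditory spectrogram.** The waveform (downmixed to mono, resampled to
16 kHz) is analysed with 40-ms Hann windows hopped every 4 ms (250 Hz
frame rate). Each of 128 cochlear channels — centres geometric over 5.3
octaves from 110 Hz, covering speech f0 and formants — takes a weighted
sum of STFT magnitude bins. The channel weight profile is an asymmetric
piecewise Gaussian in linear frequency: low-side width `fc·(2^Δ − 1)`
and high-side width `fc·(2^(Δ/2) − 1)` with Δ the channel spacing in
octaves (shallow low-frequency skirt, steep high-frequency skirt, Q
constant across channels), floored at the 25-Hz resolution of the 40-ms
window. This magnitude-STFT formulation is an envelope detector per
channel per window: non-negative, exactly homogeneous in input
amplitude, and constant-Q — the properties the rest of the pipeline
relies on. A rectify-and-smooth filterbank implementation would satisfy
the same contracts at far higher cost; the package's tests are
deliberately shape-agnostic so either cochlear stage passes them.

The 4-ms hop matters: with non-overlapping 40-ms windows the frame rate
would be 25 Hz and temporal modulations above 12.5 Hz — half of the rate
axis — would be unrepresentable. With overlapping windows a 15-s frame
spans ~3750–3840 analysis windows and the modulation Nyquist is 125 Hz.

**Modulation filtering.** The spectrogram s(t, x) (x = log-frequency) is
taken into the 2-D modulation domain by `fft2`. Axes there are temporal
modulation ω (Hz, "rate") and spectral modulation κ (cyc/oct, "scale").
For each filter centre the spectrum is weighted by a separable Gaussian
in log2(ω) and log2(κ) — constant-Q, with adjacent filters on the
centre grid crossing at −3 dB; centres: scales {0.71 … 8} cyc/oct, rate
magnitudes {0.25 … 32} Hz, both signs. Only the ω > 0 half-plane is
kept (analytic signal), so the inverse transform's magnitude is a proper
modulation envelope; within it, the quadrant sign(κ) = sign(rate)
selects sweep direction. Positive rates mark temporal modulations
coupled with *downward* frequency sweeps. The unpaired Nyquist bin of an
even-length spectral axis carries both signs at once and is excluded
from every filter, which makes time reversal mirror the signed-rate axis
exactly. Zero modulation frequency gets zero weight in every filter
(log-Gaussian limit), so a time-constant spectrogram produces no rate
energy. Filter centres beyond the modulation-domain Nyquist are
truncated with a warning and recorded in the tensor's provenance.

**Frames.** The 4-D magnitude tensor (time × 128 channels × 8 scales ×
22 signed rates) is averaged over non-overlapping 15-s frames aligned to
the recording start (trailing remainder dropped) and flattened in
(channel, scale, rate) order: 128 × 8 × 22 = 22,528 features per frame.
`stm_frame_features` streams this per filter so the full tensor is never
materialised for long recordings.

## Classification protocol

Frames are labelled *before* / *after* deprivation. Dimensionality is
reduced by PCA — 250 components at the population level, 30 at the
participant level — and classified by an RBF-kernel SVM whose
hyperparameters (C ∈ {0.1, 1, 10, 100}, γ ∈ {0.1, 1, 10}/d with d the
reduced dimensionality) are chosen by grid search under stratified
5-fold inner cross-validation scored by balanced accuracy
(BAcc = (sensitivity + specificity)/2). Outer evaluation uses either 50
repeated class-stratified 25% holdouts or leave-one-subject-out (LOSO;
population level only — with a single subject there is no one to leave
out). Split-level BAccs are summarised and tested against 0.5 with a
two-sided one-sample t-test, as the protocol prescribes; repeated
holdout splits share training data, so this test is a convention of the
protocol rather than an exact test with independent replicates.

Two leakage rules are enforced and audited in the test suite: the PCA is
fitted on training frames only (a switch reproduces the optimistic
whole-dataset variant), and at the participant level the basis is fitted
on all *other* participants' frames, so the target participant never
shapes their own reduced space. Features are centred (by the PCA) but
not variance-scaled: scaling would distort the energy interpretation of
the masks downstream.

**Within/across control.** For each participant, classifiers are
trained to discriminate every unordered pair of sessions (3 + 3 sessions
give 6 within-state and 9 across-state pairs), reusing the
participant-level reducer. Pair accuracies are averaged per group,
converted to rationalized arcsine units (RAU = (146/π)·2·arcsin√p − 23,
variance-stabilising near ceiling), and compared with a paired two-
tailed t-test across participants. Session pairs can be as small as six
frames, so the pair splits hold out at least one frame of each session.

## Reverse-correlation interpretation

A fitted classifier is probed with pseudo-random noise in its reduced
space: independent Gaussian per dimension, scaled by that dimension's
training SD (amplitude 1.0 by default — the probe amplitude is a free
calibration parameter of the method). Probe count is 100 × the number of
frames; probes perturb frames round-robin so every frame receives an
equal share. The mask is mean(probes → "after") − mean(probes →
"before"), mapped to the 22,528-feature space through the PCA
components; positive values mark features whose energy pushes the
decision toward "after deprivation". Averaging by *decision* is the
default; a `correct_only` switch restricts to probes whose decision
matches the perturbed frame's true label. Mask reliability is
quantified by pairwise Pearson correlations across the per-split
classifier replicates (p-values use df = mask length − 2).

## Interpretation-PCA

Per-participant mean masks (across that participant's split classifiers;
averaging reduces probe noise and the replicates are highly correlated)
enter a PCA across participants. Latent coordinates are expressed in
units of component-score SD — the only reading under which the fixed
idealized-mask grid of 30 points on [−2, 2] is scale-free. Traversing
one dimension (others at 0) and inverting yields idealized masks whose
per-feature variance maps show which STM features a dimension moves.
Sleepiness association: Pearson r between each coordinate and the
participant's after-deprivation SSS, plus the R² distribution of the
linear model SSS ~ dim1 + dim2 refitted once per mask replicate
(bootstrap over participants as the alternative when replicates are
unavailable), with a one-sample t-test of the R² values against zero.
Whether the in-sample or a cross-validated R² is the "right" summary is
left open; both modes exist and neither is privileged.

## The synthetic cohort

The generator emulates the study design: 22 participants × 6 reading
sessions (3 before, 3 after two nights of sleep restriction) of 600 s
each at 16 kHz, with one aggregate SSS report per state on the 1–7
Stanford scale (quarter-point grid, as an average of a few integer
reports). Voices are harmonic-plus-noise: a harmonic stack at f0
(~N(205, 18) Hz, all-female cohort) shaped by three formant resonances,
a spectral tilt, and a log-frequency ripple (density 2 cyc/oct, depth
5–8 dB) — the "timbre" carrier; amplitude- and pitch-modulated at a
per-talker prosodic rate drawn from 2–8 Hz with depth ~0.5 — the
"prosody" carrier; plus 1% additive noise. Utterances are synthesised
in 5-s segments with independently drawn harmonic phases (equal-power
crossfades), and the syllabic AM is phase-locked to the pitch contour.
Both choices are physically natural — speech is a sequence of
quasi-stationary phones, and prosodic pitch and energy co-vary — and
both are *load-bearing*: a fully stationary synthesis, or a random
relative phase between the two same-rate modulations, gives every
session a stable acoustic fingerprint that classifiers read as session
identity, so zero-effect cohorts would not classify at chance. RMS
(not peak) normalisation avoids a per-session gain stamp of the same
kind.

Deprivation effects are multiplicative on the two modulation depths in
"after" sessions — AM depth × (1 + prosody_effect), ripple depth ×
(1 + timbre_effect) — so the planted sign maps directly onto mask sign.
Config scalars give the cohort mean of each effect; `prosody_sd` /
`timbre_sd` (defaults 0.5 / 0.4) spread signed per-participant effects
around it, emulating the wide, signed individual variability that
motivates participant-level analysis. The SSS change is
`1.25 + 1.0 · (link·z + √(1−link²)·ε)` with z the standardised prosody
effect and ε orthogonalised noise, so the planted SSS–prosody
correlation concentrates tightly on `sss_link` (default 0.7).

**What the generator does not emulate** — and hence what passing tests
do *not* show about real data: intelligible phonetics or reading
content; within-state circadian drift (off by default via
`session_jitter = 0`, so the within/across control's "within" arm sits
at chance rather than at the elevated levels real reading sessions
show); time-of-day structure in SSS (one aggregate per state);
recording-channel variability; and any physiological coupling between
the prosody and timbre factors, which are planted independently.

## Problem sizes and numerical choices

Validation experiments run at demo scale as the package's own design:
a 32-channel filterbank (20-ms hop, scales {0.5, 1, 2} cyc/oct, rates
±{0.5 … 16} Hz) that keeps the planted effects inside the analysis
range, 31–61-s sessions (2–4 frames each), 100 simulated participants
for null calibration, 5 cohorts × 6 participants for strong-effect
detection, 10⁴ probes for linear mask recovery, and n = 200 profiles for
the sleepiness-link check. The defaults of `CohortConfig` and
`FilterbankSpec` remain the full study conditions.

Numerical conventions worth knowing: magnitude (not complex) STM values
are stored in float32; the inner grid search breaks score ties toward
the first (smallest C, then smallest γ) candidate; degenerate cases
warn rather than fail (all-one-class probe decisions, identical masks,
recordings shorter than one frame); and every random draw descends from
a named stage seed derived from the run seed, so identical configs
reproduce every output bit-identically (HDF5 digests are computed over
dataset payloads, making the manifest hash content-based).

## Known limitations

The t-test over correlated cross-validation splits is anti-conservative:
repeated holdouts share training data, so the split-level BAccs are
positively correlated and the t statistic's variance is underestimated.
On zero-effect cohorts of 100 simulated participants the per-participant
test rejects at roughly 10–17% instead of the nominal 5% (mean BAcc
stays at 0.500–0.504). The protocol keeps the plain t-test as its
convention and reports this inflation rather than substituting a
corrected resampled test; per-participant p-values from this procedure
should be read accordingly.
Population-level LOSO accuracy is expected to be weak whenever
individual effects differ in sign — that is the motivation for the
participant-level analysis, not a defect. The synthetic cohort is a
model system: results transfer to real speech only to the extent that
deprivation genuinely expresses itself as modulation-depth changes in
the 2–8 Hz rate band and near 2 cyc/oct.
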