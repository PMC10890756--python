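"""Reverse correlation: probe scaling, mask recovery, consistency."""

import numpy as np
import pytest

from voxstm.classify import RbfSvmClassifier
from voxstm.interpret import (
    ReverseCorrelator,
    generate_probes,
    mask_consistency,
    reverse_correlate,
)
from voxstm.validation import linear_mask_recovery


def test_probe_count_follows_100x_rule():
    probes = generate_probes(np.ones(5), n_frames=124)
    assert probes.probes.shape == (12400, 5)
    # cohort-scale frame counts map into the expected probe range
    for n_frames in (98, 194):
        n = generate_probes(np.ones(3), n_frames=n_frames).probes.shape[0]
        assert 9800 <= n <= 20000


def test_probe_scale_matches_training_sd(rng):
    sd = np.array([0.5, 2.0, 4.0])
    probes = generate_probes(sd, n_frames=100, probes_per_frame=200, amplitude=1.5, seed=1)
    emp = probes.probes.std(axis=0)
    assert np.allclose(emp, 1.5 * sd, rtol=0.05)
    assert np.allclose(probes.probes.mean(axis=0), 0.0, atol=0.1)


def test_invalid_probe_parameters():
    with pytest.raises(ValueError):
        generate_probes(np.ones(3), n_frames=10, amplitude=0.0)
    with pytest.raises(ValueError):
        generate_probes(np.ones(3), n_frames=0)


def test_vanishing_amplitude_leaves_decisions_unchanged(rng):
    """As probe amplitude -> 0, perturbed decisions equal unperturbed ones."""
    w = rng.standard_normal(6)
    frames = rng.standard_normal((40, 6))
    unperturbed = np.where(frames @ w > 0, "after", "before")

    def decide(z):
        return np.where(z @ w > 0, "after", "before")

    probes = generate_probes(np.ones(6), n_frames=40, probes_per_frame=5,
                             amplitude=1e-12, seed=0)
    assign = np.arange(probes.probes.shape[0]) % 40
    perturbed = decide(frames[assign] + probes.probes)
    assert np.array_equal(perturbed, unperturbed[assign])


def test_linear_classifier_mask_aligns_with_weights():
    """Reverse-correlation identity for linear rules: cosine >= 0.9."""
    assert linear_mask_recovery(seed=0, n_probes=10_000) >= 0.9


def test_mask_se_shrinks_with_probe_count(rng):
    """Doubling the probe count shrinks the mask's Monte-Carlo SE ~ sqrt(2)."""
    d = 8
    w = rng.standard_normal(d)
    frames = rng.standard_normal((20, d)) * 0.1

    def decide(z):
        return np.where(z @ w > 0, "after", "before")

    def masks(ppf, n_rep):
        out = []
        for s in range(n_rep):
            probes = generate_probes(np.ones(d), 20, probes_per_frame=ppf, seed=100 + s)
            m, _ = reverse_correlate(decide, frames, probes)
            out.append(m)
        return np.asarray(out)

    sd1 = masks(50, 24).std(axis=0, ddof=1).mean()
    sd2 = masks(100, 24).std(axis=0, ddof=1).mean()
    assert 1.15 < sd1 / sd2 < 1.75  # ~ sqrt(2) with sampling slack


def test_constant_classifier_gives_null_mask(rng):
    """A classifier ignoring its input yields a mask near zero."""
    d, n_frames = 6, 30
    frames = rng.standard_normal((n_frames, d))
    probes = generate_probes(np.ones(d), n_frames, probes_per_frame=100, seed=2)

    with pytest.warns(RuntimeWarning, match="degenerate"):
        mask_const, counts = reverse_correlate(
            lambda z: np.array(["after"] * len(z)), frames, probes)
    assert counts["before"] == 0

    # null distribution: random (information-free) decisions
    null_norms = []
    for s in range(40):
        r = np.random.default_rng(s)
        decisions = r.choice(["after", "before"], size=probes.probes.shape[0])
        mask, _ = reverse_correlate(lambda z, d=decisions: d, frames, probes)
        null_norms.append(np.linalg.norm(mask))
    assert np.linalg.norm(mask_const) <= np.percentile(null_norms, 95)


def test_correct_only_variant_requires_and_uses_labels(rng):
    w = np.zeros(4)
    w[0] = 1.0
    frames = rng.standard_normal((20, 4))
    labels = np.where(frames @ w > 0, "after", "before")
    probes = generate_probes(np.ones(4), 20, probes_per_frame=50, seed=0)

    def decide(z):
        return np.where(z @ w > 0, "after", "before")

    with pytest.raises(ValueError, match="labels"):
        reverse_correlate(decide, frames, probes, correct_only=True)
    m_all, _ = reverse_correlate(decide, frames, probes)
    m_cor, _ = reverse_correlate(decide, frames, probes, labels=labels, correct_only=True)
    # both variants recover the discriminative direction
    assert m_all[0] > 0 and m_cor[0] > 0


def test_reverse_correlator_estimator_roundtrip(rng):
    """End-to-end: the mask of an SVM on separable data points along the
    discriminative feature, mapped back to the full feature space."""
    n, d = 60, 10
    X = rng.standard_normal((n, d))
    y = np.array(["before", "after"] * (n // 2))
    X[y == "after", 0] += 5.0
    clf = RbfSvmClassifier(n_components=4, random_state=0).fit(X, y)
    rc = ReverseCorrelator(probes_per_frame=200, random_state=0).fit(clf, X, y)
    assert rc.mask_.shape == (d,)
    assert rc.n_probes_ == 200 * n
    direction = np.zeros(d)
    direction[0] = 1.0
    cos = rc.mask_ @ direction / np.linalg.norm(rc.mask_)
    assert cos > 0.8  # positive: energy on feature 0 marks "after"


# ---- mask consistency ----------------------------------------------------


def test_identical_masks_fully_consistent(rng):
    m = rng.standard_normal(500)
    stats = mask_consistency(np.tile(m, (5, 1)))
    assert np.allclose(stats.correlations, 1.0)
    assert stats.n_significant == len(stats.correlations) == 10


def test_independent_masks_uncorrelated(rng):
    M = rng.standard_normal((50, 22528))
    stats = mask_consistency(M)
    assert abs(stats.mean) <= 0.01
    assert len(stats.correlations) == 50 * 49 // 2


def test_template_plus_noise_replicates_consistent(rng):
    """Replicate masks sharing a template are highly consistent.

    With noise SD = 0.3 x template SD the expected pairwise r is
    1 / (1 + 0.09) ~ 0.92 (noise at exactly 1/3 would sit on the 0.9
    boundary itself).
    """
    template = rng.standard_normal(2000)
    M = template[None, :] + rng.standard_normal((50, 2000)) * (0.3 * template.std())
    stats = mask_consistency(M)
    assert stats.mean >= 0.9
    assert stats.min > 0.5


def test_zero_variance_mask_excluded(rng):
    M = np.vstack([rng.standard_normal((3, 100)), np.zeros(100)])
    stats = mask_consistency(M)
    assert stats.n_excluded == 3  # the 3 pairs involving the flat mask
    assert len(stats.correlations) == 3
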