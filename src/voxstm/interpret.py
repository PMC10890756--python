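"""Reverse-correlation interpretation of trained classifiers.

A trained classifier is probed with pseudo-random noise added to the
PCA-reduced representation of its frames.  Each probe perturbs one frame
(frames are cycled round-robin so every frame receives the same number of
probes) and the classifier's decision on the perturbed point is recorded.
The interpretation mask in the reduced space is

    mean(probes -> "after" decision) - mean(probes -> "before" decision),

mapped back to the full STM feature space through the reducer components.
Positive mask values mark features whose energy pushes the classifier
toward the "after deprivation" decision.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "ProbeSet",
    "ConsistencyStats",
    "generate_probes",
    "reverse_correlate",
    "ReverseCorrelator",
    "mask_consistency",
]


@dataclass
class ProbeSet:
    """Pseudo-random probes in the reduced space.

    Each probe dimension is zero-mean Gaussian with standard deviation
    ``amplitude`` times the training SD of that reduced dimension.
    """

    probes: np.ndarray  # (n_probes, d)
    amplitude: float
    seed: int | None


def generate_probes(
    train_sd: np.ndarray,
    n_frames: int,
    probes_per_frame: int = 100,
    amplitude: float = 1.0,
    seed: int | None = 0,
) -> ProbeSet:
    """Draw ``probes_per_frame * n_frames`` Gaussian probes."""
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    train_sd = np.asarray(train_sd, dtype=float)
    rng = np.random.default_rng(seed)
    n = int(probes_per_frame * n_frames)
    probes = rng.standard_normal((n, train_sd.size)) * (amplitude * train_sd)[None, :]
    return ProbeSet(probes=probes, amplitude=amplitude, seed=seed)


def reverse_correlate(
    decide,
    frames_reduced: np.ndarray,
    probes: ProbeSet | np.ndarray,
    pos_label="after",
    labels=None,
    correct_only: bool = False,
) -> tuple[np.ndarray, dict]:
    """Interpretation mask in the reduced space.

    Parameters
    ----------
    decide:
        Callable mapping an (n, d) array of reduced points to decisions.
    frames_reduced:
        The classifier's frames in the reduced space; probe ``i`` perturbs
        frame ``i % n_frames``.
    labels:
        True frame labels, only needed with ``correct_only=True``, which
        averages only probes whose decision matches the perturbed frame's
        true label (the stricter variant); the default averages by
        decision regardless of correctness.

    Returns the mask vector and a dict of decision counts.
    """
    P = probes.probes if isinstance(probes, ProbeSet) else np.asarray(probes, dtype=float)
    Z = np.asarray(frames_reduced, dtype=float)
    n_frames = Z.shape[0]
    assign = np.arange(P.shape[0]) % n_frames
    decisions = np.asarray(decide(Z[assign] + P))
    is_after = decisions == pos_label
    keep = np.ones(P.shape[0], dtype=bool)
    if correct_only:
        if labels is None:
            raise ValueError("correct_only requires true frame labels")
        keep = decisions == np.asarray(labels)[assign]
    after = is_after & keep
    before = (~is_after) & keep
    counts = {"after": int(after.sum()), "before": int(before.sum())}
    if counts["after"] == 0 or counts["before"] == 0:
        warnings.warn(
            "all probe decisions fell in one class: degenerate mask",
            RuntimeWarning,
            stacklevel=2,
        )
    mean_after = P[after].mean(axis=0) if counts["after"] else np.zeros(P.shape[1])
    mean_before = P[before].mean(axis=0) if counts["before"] else np.zeros(P.shape[1])
    return mean_after - mean_before, counts


class ReverseCorrelator(BaseEstimator):
    """Estimator wrapper: probe a fitted classifier, expose its mask.

    After :meth:`fit`, ``mask_reduced_`` is the mask in the PCA space and
    ``mask_`` its image in the full STM feature space (length 22,528 under
    the default filterbank).
    """

    def __init__(
        self,
        probes_per_frame: int = 100,
        amplitude: float = 1.0,
        correct_only: bool = False,
        random_state: int | None = 0,
    ):
        self.probes_per_frame = probes_per_frame
        self.amplitude = amplitude
        self.correct_only = correct_only
        self.random_state = random_state

    def fit(self, classifier, X_frames, y=None):
        """Probe `classifier` (a fitted RbfSvmClassifier) around `X_frames`."""
        Z = classifier.transform_reduced(X_frames)
        probes = generate_probes(
            classifier.train_sd_,
            n_frames=Z.shape[0],
            probes_per_frame=self.probes_per_frame,
            amplitude=self.amplitude,
            seed=self.random_state,
        )
        mask_reduced, counts = reverse_correlate(
            classifier.predict_reduced,
            Z,
            probes,
            pos_label=classifier.pos_label,
            labels=y,
            correct_only=self.correct_only,
        )
        self.mask_reduced_ = mask_reduced
        self.mask_ = mask_reduced @ classifier.reducer_.components_
        self.n_probes_ = probes.probes.shape[0]
        self.decision_counts_ = counts
        return self

    def transform(self, _=None):
        return self.mask_


@dataclass
class ConsistencyStats:
    """Pairwise Pearson correlations between interpretation masks."""

    correlations: np.ndarray  # upper-triangle values
    p_values: np.ndarray
    mean: float
    sd: float
    min: float
    n_significant: int
    n_excluded: int = 0
    alpha: float = 0.05


def mask_consistency(masks, alpha: float = 0.05) -> ConsistencyStats:
    """All C(n, 2) pairwise Pearson correlations between masks.

    Zero-variance masks make the correlation undefined; such pairs are
    excluded and counted in ``n_excluded``.
    """
    M = np.asarray(masks, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2:
        raise ValueError("need at least 2 masks of equal length")
    n, d = M.shape
    sd = M.std(axis=1)
    valid = sd > 0
    corrs, pvals = [], []
    n_excluded = 0
    C = np.corrcoef(M[valid]) if valid.sum() >= 2 else np.empty((0, 0))
    valid_idx = np.flatnonzero(valid)
    pos = {v: i for i, v in enumerate(valid_idx)}
    for i, j in itertools.combinations(range(n), 2):
        if not (valid[i] and valid[j]):
            n_excluded += 1
            continue
        r = float(np.clip(C[pos[i], pos[j]], -1.0, 1.0))
        # two-sided p for Pearson r with df = d - 2
        if abs(r) == 1.0:
            p = 0.0
        else:
            t = r * np.sqrt((d - 2) / (1.0 - r * r))
            p = 2.0 * stats.t.sf(abs(t), df=d - 2)
        corrs.append(r)
        pvals.append(p)
    corrs = np.asarray(corrs)
    pvals = np.asarray(pvals)
    return ConsistencyStats(
        correlations=corrs,
        p_values=pvals,
        mean=float(corrs.mean()) if corrs.size else np.nan,
        sd=float(corrs.std(ddof=1)) if corrs.size > 1 else 0.0,
        min=float(corrs.min()) if corrs.size else np.nan,
        n_significant=int((pvals < alpha).sum()),
        n_excluded=n_excluded,
        alpha=alpha,
    )
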