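"""Interpretation-PCA across per-participant masks.

The per-participant interpretation masks are themselves decomposed with a
PCA ("interpretation-PCA"), exposing the shared axes along which the
classifiers' discriminative features vary across individuals (in the
study this package models: a prosody-band axis at 2-8 Hz rates and a
voice-quality axis near 2 cyc/oct).  Latent coordinates are expressed in
units of the component-score standard deviation, so the fixed idealized-
mask grid on [-2, 2] spans +/- 2 SD regardless of mask scaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.linear_model import LinearRegression
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "MaskPCA",
    "IdealizedMaskGrid",
    "SleepinessAssociation",
    "associate_sleepiness",
]


@dataclass
class IdealizedMaskGrid:
    """Latent traversal of one interpretation-PCA dimension.

    30 points spanning exactly [-2, 2] (in score-SD units) on the chosen
    dimension, all others held at 0; `masks` are the reconstructed
    feature-space masks and `variance_map` the per-feature variance across
    the traversal — the features that the dimension moves the most.
    """

    dim: int
    latent_values: np.ndarray
    masks: np.ndarray  # (n_points, n_features)
    variance_map: np.ndarray  # (n_features,)


@dataclass
class SleepinessAssociation:
    """Association between mask coordinates and subjective sleepiness."""

    per_dim_r: np.ndarray
    per_dim_p: np.ndarray
    r2_values: np.ndarray
    r2_mean: float
    r2_sd: float
    r2_t: float
    r2_p: float
    mode: str
    n_dropped: int = 0


class MaskPCA(TransformerMixin, BaseEstimator):
    """PCA over per-participant interpretation masks.

    Attributes after fit: ``pca_`` (sklearn PCA), ``coords_``
    (n_participants x n_components, in score-SD units),
    ``explained_variance_ratio_``, ``score_scale_`` (SD of raw scores per
    component).
    """

    def __init__(self, n_components: int = 2, random_state: int | None = 0):
        self.n_components = n_components
        self.random_state = random_state

    def fit(self, masks, y=None):
        M = np.asarray(masks, dtype=float)
        if M.ndim != 2 or M.shape[0] < 3:
            raise ValueError("need at least 3 masks")
        n_comp = self.n_components
        limit = min(M.shape[0] - 1, M.shape[1])
        if n_comp > limit:
            warnings.warn(
                f"n_components clipped from {n_comp} to {limit} (too few masks)",
                RuntimeWarning,
            )
            n_comp = limit
        tol = 1e-12 * max(float(np.abs(M).max()), 1.0)
        if not np.any(M.std(axis=0) > tol):
            warnings.warn("identical masks: zero variance, degenerate PCA", RuntimeWarning)
        self.pca_ = PCA(n_components=n_comp, random_state=self.random_state)
        scores = self.pca_.fit_transform(M)
        scale = scores.std(axis=0, ddof=1)
        scale[scale == 0] = 1.0
        self.score_scale_ = scale
        self.coords_ = scores / scale
        self.explained_variance_ratio_ = self.pca_.explained_variance_ratio_
        self.n_components_ = n_comp
        return self

    def transform(self, masks) -> np.ndarray:
        """Project masks to latent coordinates in score-SD units."""
        check_is_fitted(self, "pca_")
        return self.pca_.transform(np.asarray(masks, dtype=float)) / self.score_scale_

    def inverse_transform(self, coords_sd) -> np.ndarray:
        """Reconstruct feature-space masks from SD-unit coordinates."""
        check_is_fitted(self, "pca_")
        coords_sd = np.atleast_2d(np.asarray(coords_sd, dtype=float))
        return self.pca_.inverse_transform(coords_sd * self.score_scale_)

    def idealized_masks(self, dim: int, n_points: int = 30, span: float = 2.0) -> IdealizedMaskGrid:
        """Traverse one latent dimension over [-span, span] (SD units)."""
        check_is_fitted(self, "pca_")
        if not 0 <= dim < self.n_components_:
            raise ValueError(f"dim {dim} out of range (0..{self.n_components_ - 1})")
        grid = np.linspace(-span, span, n_points)
        coords = np.zeros((n_points, self.n_components_))
        coords[:, dim] = grid
        masks = self.inverse_transform(coords)
        return IdealizedMaskGrid(
            dim=dim,
            latent_values=grid,
            masks=masks,
            variance_map=masks.var(axis=0),
        )


def associate_sleepiness(
    model: MaskPCA,
    sss: np.ndarray,
    replicate_coords: np.ndarray | None = None,
    n_dims: int = 2,
    n_boot: int = 50,
    seed: int = 0,
) -> SleepinessAssociation:
    """Correlate latent mask coordinates with sleepiness scores.

    Per-dimension Pearson r (two-sided p) between each of the first
    `n_dims` coordinates and the per-participant SSS (after-deprivation
    average), plus the R^2 distribution of the linear model
    ``SSS ~ dim1 + ... + dimK``.

    The R^2 distribution comes from repeated refits: if
    ``replicate_coords`` is given — an (n_replicates, n_participants,
    n_dims) array of coordinates of each participant's per-classifier
    replicate masks — one fit per replicate ("replicates" mode,
    mirroring the per-split classifier fits); otherwise `n_boot` bootstrap
    resamples of participants.  A one-sample t-test of the R^2 values
    against 0 is reported.
    """
    check_is_fitted(model, "pca_")
    sss = np.asarray(sss, dtype=float)
    ok = np.isfinite(sss)
    n_dropped = int((~ok).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} participants lack SSS scores; dropped", RuntimeWarning)
    coords = model.coords_[ok][:, :n_dims]
    y = sss[ok]
    r = np.empty(coords.shape[1])
    p = np.empty(coords.shape[1])
    for j in range(coords.shape[1]):
        r[j], p[j] = stats.pearsonr(coords[:, j], y)

    r2 = []
    if replicate_coords is not None:
        mode = "replicates"
        for rep in np.asarray(replicate_coords, dtype=float):
            Xr = rep[ok][:, :n_dims]
            fit = LinearRegression().fit(Xr, y)
            r2.append(fit.score(Xr, y))
    else:
        mode = "bootstrap"
        rng = np.random.default_rng(seed)
        n = len(y)
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            if np.unique(y[idx]).size < 2:
                continue
            fit = LinearRegression().fit(coords[idx], y[idx])
            r2.append(fit.score(coords[idx], y[idx]))
    r2 = np.asarray(r2)
    if r2.size > 1 and r2.std(ddof=1) > 0:
        t_stat, t_p = stats.ttest_1samp(r2, 0.0)
    else:
        t_stat, t_p = np.nan, np.nan
    return SleepinessAssociation(
        per_dim_r=r,
        per_dim_p=p,
        r2_values=r2,
        r2_mean=float(r2.mean()) if r2.size else np.nan,
        r2_sd=float(r2.std(ddof=1)) if r2.size > 1 else 0.0,
        r2_t=float(t_stat),
        r2_p=float(t_p),
        mode=mode,
        n_dropped=n_dropped,
    )
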