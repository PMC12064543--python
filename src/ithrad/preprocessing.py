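"""Image preprocessing and batch harmonization of feature tables.

Resampling and in-mask z-normalization prepare lesions for feature
extraction.  ComBat removes scanner/batch location-scale effects from
feature tables with empirical-Bayes shrinkage (normal prior on batch
means, inverse-gamma on batch variances).  Harmonization parameters are
estimated on a designated fit subset (typically the training split) and
applied to every row, which keeps validation data out of the estimate.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .containers import FeatureTable, ImageVolume, ROIMask

__all__ = ["resample_image", "normalize_intensity", "combat_harmonize"]


def resample_image(
    img: ImageVolume, target_spacing: Sequence[float], is_mask: bool = False
) -> ImageVolume:
    """Resample to a new pixel spacing, preserving physical extent.

    Linear interpolation for intensity images, nearest-neighbor when
    ``is_mask`` is set.  The output grid size is the physical extent
    divided by the new spacing, rounded to the nearest pixel.
    """
    target = tuple(float(s) for s in target_spacing)
    if len(target) != img.ndim:
        raise ValueError("target_spacing length must match image dimensionality")
    if any(s <= 0 for s in target):
        raise ValueError("target spacing must be positive")
    if target == img.spacing:
        return ImageVolume(img.data.copy(), img.spacing)
    factors = [s_in / s_out for s_in, s_out in zip(img.spacing, target)]
    new_shape = [max(1, int(round(n * f))) for n, f in zip(img.shape, factors)]
    exact = [ns / n for ns, n in zip(new_shape, img.shape)]
    out = ndimage.zoom(img.data, exact, order=0 if is_mask else 1,
                       mode="nearest", grid_mode=True)
    return ImageVolume(out, target)


def normalize_intensity(
    img: ImageVolume, mask: ROIMask, lesion_id: str = "lesion"
) -> ImageVolume:
    """Z-score the image by its in-mask statistics (mean 0, sd 1 in mask)."""
    if mask.is_empty():
        raise ValueError("mask is empty")
    vals = img.data[mask.data]
    mu, sd = vals.mean(), vals.std()
    if sd < 1e-12:
        raise ValueError(
            f"lesion {lesion_id!r}: zero in-mask intensity variance, cannot normalize"
        )
    return ImageVolume((img.data - mu) / sd, img.spacing)


def _aprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (2 * s2 + m**2) / s2


def _bprior(delta_hat: np.ndarray) -> float:
    m, s2 = delta_hat.mean(), delta_hat.var(ddof=1)
    return (m * s2 + m**3) / s2


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_sol(s_data, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4):
    """Iterative EB solution for one batch's shrunken means and variances."""
    n = s_data.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    change = 1.0
    while change > conv:
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((s_data - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.abs(g_new - g_old).max() / np.abs(g_old).max(),
            np.abs(d_new - d_old).max() / np.abs(d_old).max(),
        )
        g_old, d_old = g_new, d_new
    return g_old, d_old


def combat_harmonize(
    tab: FeatureTable,
    fit_rows: Sequence | None = None,
) -> FeatureTable:
    """Parametric empirical-Bayes ComBat batch harmonization.

    Per feature: standardize by the pooled (batch-mean-removed) variance,
    estimate per-batch location/scale on the fit rows, shrink them toward
    the across-feature prior (normal / inverse-gamma, moment-matched), and
    adjust all rows.  Batches present outside the fit rows must also occur
    within them.  Constant features pass through unchanged with a warning.
    With a single batch there is nothing to remove and the table is
    returned as-is (a copy).
    """
    if tab.batch is None:
        raise ValueError("feature table has no batch labels")
    tab.require_finite()
    batches = pd.unique(tab.batch)
    if len(batches) == 1:
        return tab.copy()
    if fit_rows is None:
        fit_rows = tab.subjects
    fit_rows = list(fit_rows)
    missing = [s for s in fit_rows if s not in set(tab.subjects)]
    if missing:
        raise ValueError(f"fit_rows not in table: {missing}")
    fit_batch = tab.batch.loc[fit_rows]
    fit_batches = pd.unique(fit_batch)
    absent = set(tab.batch) - set(fit_batches)
    if absent:
        raise ValueError(f"batches absent from fit rows: {sorted(map(str, absent))}")
    counts = fit_batch.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(
            f"each batch needs >= 3 fit subjects; too small: {dict(small)}"
        )

    X_fit = tab.values.loc[fit_rows].to_numpy()          # (n_fit, F)
    X_all = tab.values.to_numpy()
    n_fit = X_fit.shape[0]

    const = X_fit.std(axis=0) < 1e-12
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant feature(s) passed through ComBat unchanged",
            stacklevel=2,
        )

    batch_idx_fit = {b: np.flatnonzero((fit_batch == b).to_numpy()) for b in fit_batches}
    n_b = {b: len(ix) for b, ix in batch_idx_fit.items()}

    # batch means on fit rows; grand mean weighted by batch size
    gamma_hat = np.stack([X_fit[ix].mean(axis=0) for b, ix in batch_idx_fit.items()])
    weights = np.array([n_b[b] / n_fit for b in fit_batches])
    grand = weights @ gamma_hat                                      # (F,)
    fitted = np.zeros_like(X_fit)
    for bi, b in enumerate(fit_batches):
        fitted[batch_idx_fit[b]] = gamma_hat[bi]
    var_pooled = ((X_fit - fitted) ** 2).mean(axis=0)                # (F,)
    sd_pooled = np.sqrt(np.where(const, 1.0, var_pooled))

    def standardize(X, batch_series):
        return (X - grand[None, :]) / sd_pooled[None, :]

    Z_fit = standardize(X_fit, fit_batch)

    gamma_star = np.zeros((len(fit_batches), X_fit.shape[1]))
    delta_star = np.ones_like(gamma_star)
    active = ~const
    for bi, b in enumerate(fit_batches):
        zb = Z_fit[batch_idx_fit[b]][:, active]
        g_hat = zb.mean(axis=0)
        d_hat = zb.var(axis=0, ddof=1)
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        a, bp = _aprior(d_hat), _bprior(d_hat)
        g_star, d_star = _it_sol(zb, g_hat, d_hat, g_bar, t2, a, bp)
        gamma_star[bi, active] = g_star
        delta_star[bi, active] = d_star

    Z_all = standardize(X_all, tab.batch)
    out = np.empty_like(X_all)
    b_pos = {b: i for i, b in enumerate(fit_batches)}
    for b in batches:
        rows = np.flatnonzero((tab.batch == b).to_numpy())
        bi = b_pos[b]
        adj = (Z_all[rows] - gamma_star[bi][None, :]) / np.sqrt(delta_star[bi])[None, :]
        out[rows] = adj * sd_pooled[None, :] + grand[None, :]
    out[:, const] = X_all[:, const]
    values = pd.DataFrame(out, index=tab.values.index, columns=tab.values.columns)
    return FeatureTable(values, tab.batch.copy())
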