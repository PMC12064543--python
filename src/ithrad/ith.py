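"""Habitat clustering and the ITH-score.

A tumor's in-mask pixels are clustered on their local radiomic signatures
(k-means, per lesion), producing a *label map* of spatial habitats.  The
dispersion of those habitats is summarised by the ITH-score

    ITH = 1 - (1/S_total) * sum_i  S_i,max / n_i

where, for each nonempty cluster i, ``n_i`` is its number of connected
regions, ``S_i,max`` the pixel area of the largest such region, and
``S_total`` the total tumor area.  A tumor whose every habitat forms a
single connected blob scores 0; the score grows toward 1 as habitats
shatter into many small islands.  Scores from several cluster counts
(k = 2..5 by default) are concatenated into a feature vector for
downstream risk models.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import ndimage
from sklearn.cluster import KMeans

from .containers import ImageVolume, ROIMask
from .features import LocalFeatureConfig, PixelFeatureMap, extract_pixel_features

__all__ = [
    "LabelMap",
    "LabelMapSummary",
    "ITHResult",
    "cluster_pixels",
    "summarize_label_map",
    "compute_ith_score",
    "ith_feature_vector",
    "render_label_map",
]


def _cc_structure(ndim: int, connectivity: int) -> np.ndarray:
    """Connected-component structuring element.

    2D: connectivity 4 (edges) or 8 (edges+corners).
    3D: connectivity 6 (faces) or 26 (full cube).
    """
    if ndim == 2:
        if connectivity == 4:
            return ndimage.generate_binary_structure(2, 1)
        if connectivity == 8:
            return ndimage.generate_binary_structure(2, 2)
    elif ndim == 3:
        if connectivity == 6:
            return ndimage.generate_binary_structure(3, 1)
        if connectivity == 26:
            return ndimage.generate_binary_structure(3, 3)
    raise ValueError(f"unsupported connectivity {connectivity} for ndim={ndim}")


@dataclasses.dataclass
class LabelMap:
    """Per-pixel cluster assignment on the mask support.

    ``labels`` is an integer array on the full grid: 0 outside the mask,
    values in 1..k inside.  Clusters that ended up empty after fitting are
    simply absent from the array; ``k`` records the requested count.
    """

    labels: np.ndarray
    k: int
    lesion_id: str = "lesion"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim not in (2, 3):
            raise ValueError("label map must be 2D or 3D")
        inside = self.labels[self.labels > 0]
        if inside.size and inside.max() > self.k:
            raise ValueError("labels exceed requested cluster count k")

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    def present_labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels) if v > 0)


@dataclasses.dataclass
class ClusterComponentStats:
    area: int       # total pixels carrying this label
    n_regions: int  # connected components within the label
    s_max: int      # area of the largest component


@dataclasses.dataclass
class LabelMapSummary:
    """Connected-component statistics feeding the ITH-score."""

    s_total: int
    clusters: dict[int, ClusterComponentStats]
    connectivity: int

    @property
    def v(self) -> int:
        """Number of nonempty clusters."""
        return len(self.clusters)

    def validate(self) -> None:
        total = sum(c.area for c in self.clusters.values())
        if total != self.s_total:
            raise ValueError(
                f"cluster areas sum to {total}, expected S_total={self.s_total}"
            )
        for lab, c in self.clusters.items():
            if not (1 <= c.n_regions and 1 <= c.s_max <= c.area):
                raise ValueError(f"inconsistent component stats for cluster {lab}: {c}")


@dataclasses.dataclass
class ITHResult:
    """Per-k ITH-scores plus the integrated feature vector."""

    per_k: dict[int, float]
    integrated_ks: tuple[int, ...]
    connectivity: int
    lesion_id: str = "lesion"

    @property
    def integrated(self) -> np.ndarray:
        """Concatenated score vector over ``integrated_ks`` (model input)."""
        return np.array([self.per_k[k] for k in self.integrated_ks])


def _majority_filter(labels: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """One pass of a 3x3 (3x3x3 in 3D) in-mask majority vote.

    Suppresses single-pixel speckle in the label map before component
    counting; ties keep the current label.  Out-of-mask pixels never vote.
    """
    out = labels.copy()
    present = [v for v in np.unique(labels) if v > 0]
    counts = np.stack([
        ndimage.uniform_filter((labels == v).astype(float), size=3,
                               mode="constant", cval=0.0)
        for v in present
    ])
    best = np.argmax(counts, axis=0)
    best_cnt = np.take_along_axis(counts, best[None], axis=0)[0]
    cur_cnt = np.zeros_like(best_cnt)
    for vi, v in enumerate(present):
        cur_cnt[labels == v] = counts[vi][labels == v]
    replace = mask & (best_cnt > cur_cnt + 1e-12)
    out[replace] = np.asarray(present)[best[replace]]
    return out


def _smooth_feature_maps(pfm: PixelFeatureMap, sigma: float) -> np.ndarray:
    """Normalized (in-mask) Gaussian smoothing of each feature map."""
    mask = np.zeros(pfm.grid_shape, dtype=float)
    mask[tuple(pfm.coords.T)] = 1.0
    wsum = ndimage.gaussian_filter(mask, sigma)
    out = np.empty_like(pfm.values)
    idx = tuple(pfm.coords.T)
    full = np.zeros(pfm.grid_shape)
    for j in range(pfm.values.shape[1]):
        full[:] = 0.0
        full[idx] = pfm.values[:, j]
        sm = ndimage.gaussian_filter(full, sigma) / np.maximum(wsum, 1e-12)
        out[:, j] = sm[idx]
    return out


def cluster_pixels(pfm: PixelFeatureMap, k: int, seed: int | None = 0,
                   n_init: int = 10, max_iter: int = 300,
                   smooth_sigma_frac: float = 0.22,
                   majority_filter: bool = True) -> LabelMap:
    """K-means the per-pixel features of one lesion into ``k`` habitats.

    Before clustering, each feature map is smoothed within the mask at a
    scale proportional to the lesion's equivalent radius
    (``smooth_sigma_frac * sqrt(area/pi)``), so habitats are resolved at a
    fixed number of effective spatial cells per lesion regardless of its
    size; pixel-scale noise otherwise shatters the label map of any noisy
    lesion into spurious islands.  Features are then z-scored within the
    lesion so mixed scales do not dominate the Euclidean metric
    (zero-variance features are ignored), and the fitted label map gets
    one 3x3 in-mask majority vote against single-pixel speckle.
    Clustering is per lesion and fully deterministic given ``seed``.
    """
    n = pfm.n_pixels
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds in-mask pixel count {n}")
    if smooth_sigma_frac > 0:
        sigma = smooth_sigma_frac * np.sqrt(n / np.pi)
        X = _smooth_feature_maps(pfm, sigma)
    else:
        X = pfm.values.astype(float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 1e-12
    if keep.any():
        Z = (X[:, keep] - mu[keep]) / sd[keep]
    else:  # completely constant lesion: all pixels identical
        Z = np.zeros((n, 1))
    if k == 1:
        assign = np.zeros(n, dtype=int)
    else:
        km = KMeans(
            n_clusters=k,
            n_init=n_init,
            max_iter=max_iter,
            random_state=None if seed is None else int(seed) % (2**32 - 1),
        )
        assign = km.fit_predict(Z)
    labels = np.zeros(pfm.grid_shape, dtype=int)
    labels[tuple(pfm.coords.T)] = assign + 1
    if majority_filter and k > 1:
        labels = _majority_filter(labels, labels > 0)
    return LabelMap(labels=labels, k=k, lesion_id=pfm.lesion_id, seed=seed)


def summarize_label_map(lm: LabelMap, connectivity: int | None = None) -> LabelMapSummary:
    """Connected-component statistics per cluster (exact integer counts)."""
    if not lm.mask.any():
        raise ValueError("empty label map: no in-mask pixels")
    if connectivity is None:
        connectivity = 4 if lm.labels.ndim == 2 else 6
    structure = _cc_structure(lm.labels.ndim, connectivity)
    clusters: dict[int, ClusterComponentStats] = {}
    for lab in lm.present_labels():
        binary = lm.labels == lab
        comp, n_regions = ndimage.label(binary, structure=structure)
        sizes = np.bincount(comp.ravel())[1:]
        clusters[lab] = ClusterComponentStats(
            area=int(binary.sum()),
            n_regions=int(n_regions),
            s_max=int(sizes.max()),
        )
    return LabelMapSummary(
        s_total=int(lm.mask.sum()), clusters=clusters, connectivity=connectivity
    )


def compute_ith_score(summary: LabelMapSummary) -> float:
    """Evaluate ITH = 1 - (1/S_total) * sum_i S_i,max / n_i.

    The sum runs over nonempty clusters.  The score lies in [0, 1): it is 0
    exactly when every cluster is a single connected region, and approaches
    1 as clusters fragment into many equally small islands.
    """
    if summary.s_total < 1:
        raise ValueError("S_total must be >= 1")
    summary.validate()
    acc = sum(c.s_max / c.n_regions for c in summary.clusters.values())
    score = 1.0 - acc / summary.s_total
    # float round-off can leave a tiny negative residue on exact-zero cases
    return float(max(score, 0.0))


def ith_score_of_labels(labels: np.ndarray, connectivity: int = 4) -> float:
    """Convenience: ITH-score straight from an integer label array."""
    lm = LabelMap(labels=labels, k=int(labels.max()) if labels.max() > 0 else 1)
    return compute_ith_score(summarize_label_map(lm, connectivity=connectivity))


def ith_feature_vector(
    img: ImageVolume,
    mask: ROIMask,
    ks: Iterable[int] = (2, 3, 4, 5),
    seed: int | None = 0,
    local_cfg: LocalFeatureConfig | None = None,
    connectivity: int | None = None,
    n_init: int = 10,
    lesion_id: str = "lesion",
) -> ITHResult:
    """Full per-lesion pipeline: pixel features -> clustering -> ITH-scores.

    Runs the per-pixel extraction once, then clusters at each requested k
    (2..8 supported; 2..5 is the default integration range) and scores the
    resulting label maps.  The same seed drives every k, so the whole
    result is reproducible.
    """
    if mask.is_empty():
        raise ValueError("mask is empty")
    ks = tuple(sorted(set(int(k) for k in ks)))
    if any(k < 1 for k in ks):
        raise ValueError("cluster counts must be >= 1")
    if connectivity is None:
        connectivity = 4 if img.ndim == 2 else 6
    pfm = extract_pixel_features(img, mask, local_cfg, lesion_id=lesion_id)
    per_k: dict[int, float] = {}
    for k in ks:
        lm = cluster_pixels(pfm, k, seed=seed, n_init=n_init)
        per_k[k] = compute_ith_score(summarize_label_map(lm, connectivity=connectivity))
    return ITHResult(per_k=per_k, integrated_ks=ks, connectivity=connectivity,
                     lesion_id=lesion_id)


# fixed categorical palette (RGBA); distinct for up to 10 labels
_PALETTE = np.array([
    [0.122, 0.467, 0.706, 1.0],
    [1.000, 0.498, 0.055, 1.0],
    [0.173, 0.627, 0.173, 1.0],
    [0.839, 0.153, 0.157, 1.0],
    [0.580, 0.404, 0.741, 1.0],
    [0.549, 0.337, 0.294, 1.0],
    [0.890, 0.467, 0.761, 1.0],
    [0.498, 0.498, 0.498, 1.0],
    [0.737, 0.741, 0.133, 1.0],
    [0.090, 0.745, 0.812, 1.0],
])


def render_label_map(lm: LabelMap, path: str | Path | None = None) -> np.ndarray:
    """Color the label map with a stable categorical palette.

    Background pixels are transparent black.  Returns the RGBA array; if
    ``path`` is given the image is also written there (PNG).
    """
    if lm.labels.ndim != 2:
        raise ValueError("rendering supports 2D label maps")
    rgba = np.zeros(lm.labels.shape + (4,), dtype=float)
    for lab in lm.present_labels():
        rgba[lm.labels == lab] = _PALETTE[(lab - 1) % len(_PALETTE)]
    if path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        plt.imsave(str(path), rgba)
    return rgba
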