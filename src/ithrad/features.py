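"""Radiomic feature extraction and the three-stage feature filter.

Two extraction modes:

* whole-ROI — one named feature vector per lesion (first-order statistics
  plus GLCM / GLRLM / GLSZM texture on the discretized in-mask image);
* per-pixel — a local feature vector for every in-mask pixel, computed on
  the square neighborhood of radius ``r`` clipped to the mask.  These maps
  are the input to habitat clustering.

Feature refinement follows the fixed order: segmentation-stability ICC
filter, then minimum-redundancy-maximum-relevance (mRMR) ranking, then
L1-penalized logistic (lasso) selection.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, mutual_info_score
from sklearn.model_selection import StratifiedKFold

from .containers import FeatureTable, ImageVolume, ROIMask

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureConfig",
    "LocalFeatureConfig",
    "PixelFeatureMap",
    "extract_whole_roi_features",
    "extract_pixel_features",
    "icc_two_way_random",
    "icc_stability_filter",
    "mrmr_select",
    "lasso_select",
]


# ---------------------------------------------------------------------------
# configuration


@dataclasses.dataclass
class FeatureConfig:
    """Whole-ROI extraction settings.

    ``bins`` controls gray-level discretization (fixed bin count over the
    in-mask intensity range, recomputed per lesion).  ``families`` selects
    which groups are extracted.  GLCM/GLRLM use the four in-plane unit
    offsets (0, 45, 90, 135 degrees) at distance 1 and average each feature
    over offsets.
    """

    bins: int = 32
    families: tuple[str, ...] = ("firstorder", "glcm", "glrlm", "glszm")
    aggregation: str = "mean"

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        valid = {"firstorder", "glcm", "glrlm", "glszm"}
        if not self.families or not set(self.families) <= valid:
            raise ValueError(f"families must be a nonempty subset of {valid}")


#: default per-pixel feature set used for habitat clustering.  Intensity
#: statistics dominate deliberately: in lesions whose habitats differ mainly
#: in attenuation, shape-free moments such as skewness/kurtosis and the GLCM
#: correlation carry no habitat signal but are spatially autocorrelated, and
#: a z-scored k-means can lock onto their coherent noise patches instead of
#: the habitats.  The extended set adds them back for users who want them.
CORE_LOCAL_FEATURES = (
    "local_mean", "local_min", "local_max", "local_energy",
)
EXTENDED_LOCAL_FEATURES = CORE_LOCAL_FEATURES + (
    "local_variance", "local_skewness", "local_kurtosis", "local_range",
    "local_entropy", "glcm_contrast", "glcm_dissimilarity",
    "glcm_homogeneity", "glcm_correlation",
)


@dataclasses.dataclass
class LocalFeatureConfig:
    """Per-pixel extraction settings: window radius, entropy bins, feature set."""

    radius: int = 2
    bins: int = 16
    features: tuple[str, ...] = CORE_LOCAL_FEATURES

    def __post_init__(self) -> None:
        if self.radius < 1:
            raise ValueError("window radius must be >= 1")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        unknown = set(self.features) - set(EXTENDED_LOCAL_FEATURES)
        if unknown:
            raise ValueError(f"unknown local features: {sorted(unknown)}")
        if not self.features:
            raise ValueError("at least one local feature is required")


@dataclasses.dataclass
class PixelFeatureMap:
    """Local feature matrix, one row per in-mask pixel."""

    coords: np.ndarray          # (N, ndim) integer pixel coordinates
    values: np.ndarray          # (N, F) feature matrix
    feature_names: list[str]
    grid_shape: tuple[int, ...]
    lesion_id: str = "lesion"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.coords.shape[0] != self.values.shape[0]:
            raise ValueError("coords and values disagree on pixel count")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names length mismatch")

    @property
    def n_pixels(self) -> int:
        return self.coords.shape[0]

    def to_frame(self) -> pd.DataFrame:
        axes = ["row", "col", "slice"][: self.coords.shape[1]]
        df = pd.DataFrame(self.coords, columns=axes)
        for j, name in enumerate(self.feature_names):
            df[name] = self.values[:, j]
        return df


# ---------------------------------------------------------------------------
# discretization helper


def _discretize(x: np.ndarray, mask: np.ndarray, bins: int) -> np.ndarray:
    """Map in-mask intensities to levels 1..bins; 0 outside the mask."""
    vals = x[mask]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(x.shape, dtype=int)
    if hi == lo:
        levels[mask] = 1
        return levels
    idx = np.floor((x - lo) / (hi - lo) * bins).astype(int)
    idx = np.clip(idx, 0, bins - 1) + 1
    levels[mask] = idx[mask]
    return levels


# ---------------------------------------------------------------------------
# whole-ROI extraction


def _first_order(vals: np.ndarray, bins: int) -> dict[str, float]:
    p = np.histogram(vals, bins=bins)[0].astype(float)
    p = p[p > 0] / vals.size
    out = {
        "mean": float(vals.mean()),
        "variance": float(vals.var()),
        "skewness": float(stats.skew(vals)) if vals.std() > 0 else 0.0,
        "kurtosis": float(stats.kurtosis(vals)) if vals.std() > 0 else 0.0,
        "minimum": float(vals.min()),
        "maximum": float(vals.max()),
        "range": float(np.ptp(vals)),
        "median": float(np.median(vals)),
        "percentile10": float(np.percentile(vals, 10)),
        "percentile90": float(np.percentile(vals, 90)),
        "iqr": float(np.percentile(vals, 75) - np.percentile(vals, 25)),
        "energy": float(np.sum(vals**2)),
        "rms": float(np.sqrt(np.mean(vals**2))),
        "mad": float(np.mean(np.abs(vals - vals.mean()))),
        "entropy": float(-np.sum(p * np.log2(p))),
        "uniformity": float(np.sum(p**2)),
    }
    return out


_OFFSETS_2D = [(0, 1), (1, 0), (1, 1), (1, -1)]


def _shift(a: np.ndarray, off: tuple[int, ...]) -> np.ndarray:
    """Shift so that out[p] = a[p + off], zero-filled at borders."""
    out = np.zeros_like(a)
    src = []
    dst = []
    for o, n in zip(off, a.shape):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    out[tuple(dst)] = a[tuple(src)]
    return out


def build_glcm(levels: np.ndarray, mask: np.ndarray, bins: int,
               offset: tuple[int, ...]) -> np.ndarray:
    """Symmetric co-occurrence matrix restricted to in-mask pixel pairs."""
    nb = _shift(levels, offset)
    valid = mask & _shift(mask, offset)
    i = levels[valid] - 1
    j = nb[valid] - 1
    glcm = np.zeros((bins, bins))
    np.add.at(glcm, (i, j), 1.0)
    glcm = glcm + glcm.T  # symmetrize: count each pair in both directions
    return glcm


def _glcm_features(glcm: np.ndarray) -> dict[str, float]:
    total = glcm.sum()
    if total == 0:
        return {k: 0.0 for k in (
            "contrast", "dissimilarity", "homogeneity", "asm", "energy",
            "entropy", "correlation")}
    p = glcm / total
    n = p.shape[0]
    i, j = np.meshgrid(np.arange(1, n + 1), np.arange(1, n + 1), indexing="ij")
    pi = p.sum(axis=1)
    mu = np.sum(np.arange(1, n + 1) * pi)
    sig2 = np.sum((np.arange(1, n + 1) - mu) ** 2 * pi)
    nz = p[p > 0]
    corr = 0.0
    if sig2 > 1e-12:
        corr = float(np.sum(p * (i - mu) * (j - mu)) / sig2)
    return {
        "contrast": float(np.sum(p * (i - j) ** 2)),
        "dissimilarity": float(np.sum(p * np.abs(i - j))),
        "homogeneity": float(np.sum(p / (1.0 + (i - j) ** 2))),
        "asm": float(np.sum(p**2)),
        "energy": float(np.sqrt(np.sum(p**2))),
        "entropy": float(-np.sum(nz * np.log2(nz))),
        "correlation": corr,
    }


def _runs_along(line_levels: np.ndarray) -> list[tuple[int, int]]:
    """Run-length encode one line; level 0 (outside mask) breaks runs."""
    runs = []
    prev = 0
    length = 0
    for v in line_levels:
        if v == prev and v != 0:
            length += 1
        else:
            if prev != 0:
                runs.append((prev, length))
            prev = v
            length = 1 if v != 0 else 0
    if prev != 0:
        runs.append((prev, length))
    return runs


def _iter_lines(levels: np.ndarray, direction: tuple[int, int]):
    """Yield the 1D scan lines of a 2D array along an offset direction."""
    h, w = levels.shape
    if direction == (0, 1):
        for r in range(h):
            yield levels[r, :]
    elif direction == (1, 0):
        for c in range(w):
            yield levels[:, c]
    elif direction == (1, 1):
        for off in range(-h + 1, w):
            yield np.diagonal(levels, offset=off)
    elif direction == (1, -1):
        fl = levels[:, ::-1]
        for off in range(-h + 1, w):
            yield np.diagonal(fl, offset=off)
    else:  # pragma: no cover
        raise ValueError(f"unsupported direction {direction}")


def _glrlm_features(levels: np.ndarray, bins: int, n_pixels: int) -> dict[str, float]:
    feats: dict[str, list[float]] = {}
    for direction in _OFFSETS_2D:
        counts: dict[tuple[int, int], float] = {}
        for line in _iter_lines(levels, direction):
            for lev, ln in _runs_along(np.asarray(line)):
                counts[(lev, ln)] = counts.get((lev, ln), 0.0) + 1.0
        nr = sum(counts.values())
        if nr == 0:
            vals = dict.fromkeys(
                ["sre", "lre", "gln", "rln", "rp", "lglre", "hglre"], 0.0)
        else:
            levs = np.array([k[0] for k in counts], dtype=float)
            lens = np.array([k[1] for k in counts], dtype=float)
            r = np.array(list(counts.values()))
            by_level = pd.Series(r).groupby(levs).sum().to_numpy()
            by_len = pd.Series(r).groupby(lens).sum().to_numpy()
            vals = {
                "sre": float(np.sum(r / lens**2) / nr),
                "lre": float(np.sum(r * lens**2) / nr),
                "gln": float(np.sum(by_level**2) / nr),
                "rln": float(np.sum(by_len**2) / nr),
                "rp": float(nr / n_pixels),
                "lglre": float(np.sum(r / levs**2) / nr),
                "hglre": float(np.sum(r * levs**2) / nr),
            }
        for k, v in vals.items():
            feats.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in feats.items()}


def _glszm_features(levels: np.ndarray, mask: np.ndarray, bins: int,
                    n_pixels: int) -> dict[str, float]:
    structure = ndimage.generate_binary_structure(2, 2)  # zones use 8-connectivity
    zone_levels: list[int] = []
    zone_sizes: list[int] = []
    for lev in range(1, bins + 1):
        binary = (levels == lev) & mask
        if not binary.any():
            continue
        comp, n = ndimage.label(binary, structure=structure)
        sizes = np.bincount(comp.ravel())[1:]
        zone_levels.extend([lev] * n)
        zone_sizes.extend(sizes.tolist())
    nz = len(zone_sizes)
    if nz == 0:
        return dict.fromkeys(["sae", "lae", "gln", "zsn", "zp", "lglze", "hglze"], 0.0)
    levs = np.array(zone_levels, dtype=float)
    szs = np.array(zone_sizes, dtype=float)
    by_level = pd.Series(np.ones(nz)).groupby(levs).sum().to_numpy()
    by_size = pd.Series(np.ones(nz)).groupby(szs).sum().to_numpy()
    return {
        "sae": float(np.sum(1.0 / szs**2) / nz),
        "lae": float(np.sum(szs**2) / nz),
        "gln": float(np.sum(by_level**2) / nz),
        "zsn": float(np.sum(by_size**2) / nz),
        "zp": float(nz / n_pixels),
        "lglze": float(np.sum(1.0 / levs**2) / nz),
        "hglze": float(np.sum(levs**2) / nz),
    }


def _largest_slice(mask: np.ndarray) -> int:
    areas = mask.reshape(-1, mask.shape[2]).sum(axis=0) if mask.ndim == 3 else None
    return int(np.argmax(areas))


def extract_whole_roi_features(
    img: ImageVolume, mask: ROIMask, cfg: FeatureConfig | None = None
) -> pd.Series:
    """Whole-ROI radiomics vector for one lesion.

    3D inputs are analysed on the largest-area mask slice (in-plane texture);
    first-order statistics then also restrict to that slice so every feature
    describes the same pixel set.
    """
    cfg = cfg or FeatureConfig()
    if mask.is_empty():
        raise ValueError("mask is empty")
    data, m = img.data, mask.data
    if data.ndim == 3:
        s = _largest_slice(m)
        data, m = data[:, :, s], m[:, :, s]
    n_pixels = int(m.sum())
    texture_requested = bool(set(cfg.families) & {"glcm", "glrlm", "glszm"})
    if n_pixels < 2 and texture_requested:
        raise ValueError("single-pixel ROI cannot support texture features")
    vals = data[m]
    out: dict[str, float] = {}
    if "firstorder" in cfg.families:
        for k, v in _first_order(vals, cfg.bins).items():
            out[f"firstorder_{k}"] = v
    if texture_requested:
        levels = _discretize(data, m, cfg.bins)
        if "glcm" in cfg.families:
            per_off = [
                _glcm_features(build_glcm(levels, m, cfg.bins, off))
                for off in _OFFSETS_2D
            ]
            for k in per_off[0]:
                out[f"glcm_{k}"] = float(np.mean([d[k] for d in per_off]))
        if "glrlm" in cfg.families:
            for k, v in _glrlm_features(levels, cfg.bins, n_pixels).items():
                out[f"glrlm_{k}"] = v
        if "glszm" in cfg.families:
            for k, v in _glszm_features(levels, m, cfg.bins, n_pixels).items():
                out[f"glszm_{k}"] = v
    return pd.Series(out, dtype=float)


# ---------------------------------------------------------------------------
# per-pixel extraction


def _win_sum(a: np.ndarray, size: int) -> np.ndarray:
    """Sum over the centered square window (zero-padded at borders)."""
    vol = size ** a.ndim
    return ndimage.uniform_filter(a, size=size, mode="constant", cval=0.0) * vol


def extract_pixel_features(
    img: ImageVolume,
    mask: ROIMask,
    cfg: LocalFeatureConfig | None = None,
    lesion_id: str = "lesion",
) -> PixelFeatureMap:
    """Local feature vector for every in-mask pixel.

    Statistics use the square window of radius ``cfg.radius`` intersected
    with the mask, so out-of-mask intensities never leak in.  First-order
    moments come from masked windowed sums; entropy from a windowed
    histogram of the discretized image; the GLCM block from windowed means
    over valid in-mask pixel pairs at the unit offsets, averaged over
    offsets.  Pixels whose neighborhood degenerates to themselves get zero
    texture (logged, not an error) so boundary pixels remain usable.
    """
    cfg = cfg or LocalFeatureConfig()
    if mask.is_empty():
        raise ValueError("mask is empty")
    wanted = set(cfg.features)
    x = np.where(mask.data, img.data, 0.0)
    m = mask.data.astype(float)
    size = 2 * cfg.radius + 1
    eps = 1e-10
    feature_arrays: dict[str, np.ndarray] = {}

    cnt = _win_sum(m, size)
    cnt_safe = np.maximum(cnt, eps)
    m1 = _win_sum(x, size) / cnt_safe
    m2 = _win_sum(x**2, size) / cnt_safe
    var = np.maximum(m2 - m1**2, 0.0)
    feature_arrays["local_mean"] = m1
    feature_arrays["local_energy"] = m2
    feature_arrays["local_variance"] = var
    if wanted & {"local_skewness", "local_kurtosis"}:
        m3 = _win_sum(x**3, size) / cnt_safe
        m4 = _win_sum(x**4, size) / cnt_safe
        sd = np.sqrt(var)
        ok = var > eps
        with np.errstate(divide="ignore", invalid="ignore"):
            feature_arrays["local_skewness"] = np.where(
                ok, (m3 - 3 * m1 * m2 + 2 * m1**3) / np.maximum(sd, eps) ** 3, 0.0)
            feature_arrays["local_kurtosis"] = np.where(
                ok,
                (m4 - 4 * m1 * m3 + 6 * m1**2 * m2 - 3 * m1**4)
                / np.maximum(var, eps) ** 2 - 3.0,
                0.0,
            )
    if wanted & {"local_min", "local_max", "local_range"}:
        inf = np.inf
        mn = ndimage.minimum_filter(np.where(mask.data, img.data, inf), size=size,
                                    mode="constant", cval=inf)
        mx = ndimage.maximum_filter(np.where(mask.data, img.data, -inf), size=size,
                                    mode="constant", cval=-inf)
        feature_arrays["local_min"] = mn
        feature_arrays["local_max"] = mx
        feature_arrays["local_range"] = mx - mn

    glcm_wanted = {f for f in wanted if f.startswith("glcm_")}
    need_levels = bool(glcm_wanted) or "local_entropy" in wanted
    if need_levels:
        levels = _discretize(img.data, mask.data, cfg.bins)
    if "local_entropy" in wanted:
        # windowed histogram -> entropy
        ent = np.zeros_like(x)
        for lev in range(1, cfg.bins + 1):
            c = _win_sum((levels == lev).astype(float), size)
            p = c / cnt_safe
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(p > 0, -p * np.log2(np.maximum(p, eps)), 0.0)
            ent += term
        feature_arrays["local_entropy"] = ent

    if glcm_wanted:
        # pairwise (GLCM-style) block, averaged over unit offsets
        if img.ndim == 2:
            offsets = _OFFSETS_2D
        else:
            offsets = [(0, 1, 0), (1, 0, 0), (0, 0, 1)]
        L = levels.astype(float)
        acc = {k: np.zeros_like(x) for k in
               ("contrast", "dissimilarity", "homogeneity", "correlation")}
        n_valid = np.zeros_like(x)
        for off in offsets:
            Ls = _shift(L, off)
            v = (mask.data & _shift(mask.data, off)).astype(float)
            cp = _win_sum(v, size)
            has = cp > eps
            cp_safe = np.maximum(cp, eps)
            d = (L - Ls) * v
            if "glcm_correlation" in wanted:
                e1 = _win_sum(L * v, size) / cp_safe
                e2 = _win_sum(Ls * v, size) / cp_safe
                e11 = _win_sum(L * Ls * v, size) / cp_safe
                v1 = np.maximum(_win_sum(L**2 * v, size) / cp_safe - e1**2, 0.0)
                v2 = np.maximum(_win_sum(Ls**2 * v, size) / cp_safe - e2**2, 0.0)
                denom = np.sqrt(v1 * v2)
                corr = np.where(denom > eps,
                                (e11 - e1 * e2) / np.maximum(denom, eps), 0.0)
                acc["correlation"] += np.where(has, corr, 0.0)
            acc["contrast"] += np.where(has, _win_sum(d**2, size) / cp_safe, 0.0)
            acc["dissimilarity"] += np.where(
                has, _win_sum(np.abs(d), size) / cp_safe, 0.0)
            acc["homogeneity"] += np.where(
                has, _win_sum(v / (1.0 + (L - Ls) ** 2), size) / cp_safe, 0.0)
            n_valid += has.astype(float)
        nv_safe = np.maximum(n_valid, 1.0)
        for short, arr in acc.items():
            feature_arrays[f"glcm_{short}"] = arr / nv_safe

    coords = np.argwhere(mask.data)
    idx = tuple(coords.T)
    if glcm_wanted and np.any(n_valid[idx] == 0):
        logger.warning(
            "lesion %s: %d pixel(s) with no in-mask neighbor pairs; "
            "texture features set to 0 there",
            lesion_id, int(np.sum(n_valid[idx] == 0)),
        )

    names = [f for f in cfg.features]
    values = np.stack([feature_arrays[k][idx] for k in names], axis=1)
    return PixelFeatureMap(
        coords=coords,
        values=values,
        feature_names=names,
        grid_shape=mask.data.shape,
        lesion_id=lesion_id,
    )


# ---------------------------------------------------------------------------
# feature filtering: ICC -> mRMR -> lasso


def icc_two_way_random(tab_a: FeatureTable, tab_b: FeatureTable) -> pd.Series:
    """ICC(2,1): two-way random effects, single measure, absolute agreement.

    One rating pair per subject per feature (original vs perturbed
    segmentation).  Computed per feature from the two-way ANOVA mean
    squares; features identical across readings get ICC 1 by continuity.
    """
    if tab_a.subjects != tab_b.subjects:
        raise ValueError("tables must hold the same subjects in the same order")
    if tab_a.feature_names != tab_b.feature_names:
        raise ValueError("tables must hold the same features")
    n = len(tab_a.subjects)
    if n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    A, B = tab_a.matrix, tab_b.matrix
    k = 2
    grand = (A + B).mean(axis=0) / k
    row_mean = (A + B) / k
    col_means = np.stack([A.mean(axis=0), B.mean(axis=0)])
    msr = k * ((row_mean - grand) ** 2).sum(axis=0) / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum(axis=0) / (k - 1)
    sst = ((A - grand) ** 2 + (B - grand) ** 2).sum(axis=0)
    sse = sst - msr * (n - 1) - msc * (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = (msr - mse) / denom
    exact = np.all(A == B, axis=0)
    icc = np.where(np.abs(denom) < 1e-15, np.where(exact, 1.0, 0.0), icc)
    icc = np.where(exact, 1.0, icc)
    return pd.Series(icc, index=tab_a.feature_names, name="icc")


def icc_stability_filter(
    tab_a: FeatureTable, tab_b: FeatureTable, threshold: float = 0.90
) -> list[str]:
    """Keep features whose ICC(2,1) across the two segmentations is > threshold."""
    icc = icc_two_way_random(tab_a, tab_b)
    return [name for name, v in icc.items() if np.isfinite(v) and v > threshold]


def _tertile_codes(x: np.ndarray) -> np.ndarray:
    qs = np.quantile(x, [1 / 3, 2 / 3])
    return np.digitize(x, qs)


def mrmr_select(tab: FeatureTable, labels: Sequence[int], m: int) -> list[str]:
    """Greedy mRMR ranking (MID criterion) of ``m`` features.

    Relevance and redundancy are mutual information on tertile-discretized
    features.  Selection is greedy: the next feature maximizes
    I(f; y) - mean_{s in selected} I(f; s).  Score ties break on feature
    name (lexicographic) for determinism.
    """
    if m < 0:
        raise ValueError("m must be >= 0")
    if m == 0:
        return []
    names = tab.feature_names
    if m > len(names):
        raise ValueError(f"m={m} exceeds feature count {len(names)}")
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    X = tab.matrix
    disc = np.stack([_tertile_codes(X[:, j]) for j in range(X.shape[1])], axis=1)
    order = np.argsort(names)  # scan in name order so strict > breaks ties
    relevance = {names[j]: mutual_info_score(disc[:, j], y) for j in range(len(names))}
    col = {name: j for j, name in enumerate(names)}
    selected: list[str] = []
    red_sum = dict.fromkeys(names, 0.0)
    while len(selected) < m:
        best_name, best_score = None, -np.inf
        for j in order:
            name = names[j]
            if name in selected:
                continue
            red = red_sum[name] / len(selected) if selected else 0.0
            score = relevance[name] - red
            if score > best_score + 1e-12:
                best_name, best_score = name, score
        selected.append(best_name)
        for name in names:
            if name not in selected:
                red_sum[name] += mutual_info_score(
                    disc[:, col[name]], disc[:, col[best_name]]
                )
    return selected


def lasso_select(
    tab: FeatureTable,
    labels: Sequence[int],
    folds: int = 10,
    seed: int = 0,
    c_grid: np.ndarray | None = None,
) -> tuple[list[str], pd.Series]:
    """L1-penalized logistic selection with the cross-validated 1-SE rule.

    The penalty path is scanned by stratified K-fold deviance; the chosen
    penalty is the strongest one whose mean deviance is within one standard
    error of the minimum.  Returns the nonzero-coefficient features and
    their coefficients from the final whole-data refit.
    """
    y = np.asarray(labels).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("labels must be binary with both classes present")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 subjects")
    X = tab.matrix
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 1e-12, sd, 1.0)
    Z = (X - mu) / sd
    if c_grid is None:
        c_grid = np.logspace(-3, 2, 40)
    folds = min(folds, counts.min())
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Z, y))
    mean_dev = np.empty(len(c_grid))
    se_dev = np.empty(len(c_grid))
    for i, c in enumerate(c_grid):
        devs = []
        for tr, va in splits:
            clf = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=c,
                                     max_iter=2000, random_state=seed)
            clf.fit(Z[tr], y[tr])
            p = clf.predict_proba(Z[va])[:, 1]
            devs.append(log_loss(y[va], p, labels=classes))
        devs = np.asarray(devs)
        mean_dev[i] = devs.mean()
        se_dev[i] = devs.std(ddof=1) / np.sqrt(len(devs))
    best = int(np.argmin(mean_dev))
    limit = mean_dev[best] + se_dev[best]
    # strongest penalty (smallest C) still within one SE of the best
    chosen = int(np.flatnonzero(mean_dev <= limit)[0]) if np.any(mean_dev <= limit) else best
    clf = LogisticRegression(solver="liblinear", l1_ratio=1.0, C=c_grid[chosen],
                             max_iter=2000, random_state=seed)
    clf.fit(Z, y)
    coefs = pd.Series(clf.coef_.ravel(), index=tab.feature_names)
    kept = coefs[coefs != 0.0]
    return list(kept.index), kept
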