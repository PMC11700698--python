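"""Texture-radiomics baseline: first-order + GLCM features, t-test + mRmR
selection, and a decision-tree classifier.

Features are computed on a region of interest (ROI) 200 um below the detected
skin surface.  First-order statistics use the raw ROI intensities; gray-level
co-occurrence (GLCM) features use intensities quantized to a fixed number of
gray levels, with a symmetric distance-1 matrix averaged over the four
standard directions (0, 45, 90, 135 degrees) and normalized to sum to 1.

Feature selection is two-stage: a Welch t-test gate (p < 0.05, two-sided)
followed by greedy minimum-redundancy-maximum-relevance (mRmR, MID variant:
mutual information with the label minus mean mutual information with the
already-selected features), with continuous features discretized into
quartile bins for the MI estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import mutual_info_score
from sklearn.tree import DecisionTreeClassifier

from .io_prep import SurfaceMap

#: the five features reported as most discriminative
TOP5_FEATURES = [
    "kurtosis",
    "glcm_maximum_probability",
    "glcm_joint_energy",
    "interquartile_range",
    "robust_mean_absolute_deviation",
]

#: (row, col) offsets of the four standard GLCM directions at distance 1
GLCM_OFFSETS = {
    0: (0, 1),  # 0 degrees
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}


@dataclass
class RegionOfInterest:
    """Boolean mask confined to the sub-surface band."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


def subsurface_roi(shape: tuple[int, int], surface: SurfaceMap,
                   axial_um_per_px: float, window_um: float = 200.0) -> RegionOfInterest:
    """Band [surface, surface + window_um) on usable A-lines."""
    depth, lateral = shape
    window_px = int(round(window_um / axial_um_per_px))
    rows = np.arange(depth)[:, None]
    top = surface.surface_index[None, :]
    mask = (rows >= top) & (rows < top + window_px) & surface.quality[None, :]
    return RegionOfInterest(mask=mask)


# ----------------------------------------------------------------------------
# feature extraction
# ----------------------------------------------------------------------------

def quantize(values: np.ndarray, bins: int) -> np.ndarray:
    """Equal-width quantization of intensities to gray levels 0..bins-1."""
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        return np.zeros(values.shape, dtype=np.int64)
    levels = np.floor((values - lo) / (hi - lo) * bins).astype(np.int64)
    return np.clip(levels, 0, bins - 1)


def glcm(image: np.ndarray, roi: RegionOfInterest, bins: int = 32,
         directions: tuple[int, ...] = (0, 45, 90, 135)) -> np.ndarray:
    """Symmetric distance-1 GLCM averaged over directions, summing to 1.

    Only pixel pairs whose both members lie inside the ROI contribute.  Each
    direction's matrix is normalized before averaging; directions with no
    valid pair are skipped.
    """
    image = np.asarray(image, dtype=float)
    q = np.zeros(image.shape, dtype=np.int64)
    q[roi.mask] = quantize(image[roi.mask], bins)
    mats = []
    for d in directions:
        dr, dc = GLCM_OFFSETS[d]
        h, w = image.shape
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a_mask = roi.mask[r0:r1, c0:c1]
        b_mask = roi.mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        valid = a_mask & b_mask
        if not valid.any():
            continue
        a = q[r0:r1, c0:c1][valid]
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc][valid]
        mat = np.zeros((bins, bins))
        np.add.at(mat, (a, b), 1.0)
        np.add.at(mat, (b, a), 1.0)  # symmetric
        mats.append(mat / mat.sum())
    if not mats:
        # degenerate ROI (no adjacent pairs): all mass on the single level
        mat = np.zeros((bins, bins))
        mat[0, 0] = 1.0
        return mat
    return np.mean(mats, axis=0)


def first_order_features(values: np.ndarray) -> dict[str, float]:
    """First-order statistics of raw ROI intensities.

    Kurtosis is the Pearson (non-excess) convention: a normal distribution
    scores 3.  Robust MAD is the mean absolute deviation of the 10th-90th
    percentile subset around that subset's own mean.
    """
    v = np.asarray(values, dtype=float)
    mean = float(v.mean())
    var = float(v.var())
    if var > 0:
        kurt = float(np.mean((v - mean) ** 4) / var ** 2)
        skew = float(np.mean((v - mean) ** 3) / var ** 1.5)
    else:
        kurt, skew = 0.0, 0.0
    q1, q3 = np.percentile(v, [25, 75])
    p10, p90 = np.percentile(v, [10, 90])
    sub = v[(v >= p10) & (v <= p90)]
    rmad = float(np.mean(np.abs(sub - sub.mean()))) if sub.size else 0.0
    return {
        "mean": mean,
        "median": float(np.median(v)),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
        "interquartile_range": float(q3 - q1),
        "robust_mean_absolute_deviation": rmad,
        "range": float(v.max() - v.min()),
        "percentile_10": float(p10),
        "percentile_90": float(p90),
        "energy": float(np.sum(v ** 2)),
        "mean_absolute_deviation": float(np.mean(np.abs(v - mean))),
    }


def glcm_features(p: np.ndarray) -> dict[str, float]:
    i = np.arange(p.shape[0])[:, None]
    j = np.arange(p.shape[1])[None, :]
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    sd_i = float(np.sqrt(np.sum((i - mu_i) ** 2 * p)))
    sd_j = float(np.sqrt(np.sum((j - mu_j) ** 2 * p)))
    nz = p[p > 0]
    corr = (float(np.sum((i - mu_i) * (j - mu_j) * p)) / (sd_i * sd_j)
            if sd_i > 0 and sd_j > 0 else 1.0)
    return {
        "glcm_joint_energy": float(np.sum(p ** 2)),
        "glcm_maximum_probability": float(p.max()),
        "glcm_contrast": float(np.sum((i - j) ** 2 * p)),
        "glcm_homogeneity": float(np.sum(p / (1.0 + np.abs(i - j)))),
        "glcm_joint_entropy": float(-np.sum(nz * np.log2(nz))),
        "glcm_correlation": corr,
    }


def extract_features(bscan: np.ndarray, roi: RegionOfInterest, bins: int = 32,
                     directions: tuple[int, ...] = (0, 45, 90, 135)) -> dict[str, float]:
    """The full candidate feature pool for one ROI."""
    if int(roi.mask.sum()) < 64:
        raise ValueError("ROI must contain >= 64 pixels")
    values = np.asarray(bscan, dtype=float)[roi.mask]
    feats = first_order_features(values)
    feats.update(glcm_features(glcm(bscan, roi, bins=bins, directions=directions)))
    return feats


def feature_table(bscans, rois, bins: int = 32) -> pd.DataFrame:
    return pd.DataFrame([extract_features(b, r, bins=bins)
                         for b, r in zip(bscans, rois)])


# ----------------------------------------------------------------------------
# selection: Welch t-test gate, then greedy mRmR (MID)
# ----------------------------------------------------------------------------

@dataclass
class SelectionResult:
    selected: list[str]
    t_stats: pd.Series
    p_values: pd.Series
    mrmr_scores: dict[str, float]  # score at the step each feature was picked
    survivors: list[str]  # features passing the t-test gate
    warning: str | None = None


def _quartile_bins(x: np.ndarray, n_bins: int = 4) -> np.ndarray:
    edges = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.digitize(x, np.unique(edges))


def rank_and_select(features: pd.DataFrame, labels, k: int = 5,
                    alpha: float = 0.05, mi_bins: int = 4) -> SelectionResult:
    """Two-stage feature selection.

    Stage 1 keeps features with two-sided Welch t-test p < ``alpha``.  Stage 2
    greedily ranks survivors by the MID mRmR score
    ``MI(f; y) - mean_{s in selected} MI(f; s)`` with quartile-discretized MI.
    Deterministic: ties resolve by column order.
    """
    labels = np.asarray(labels, dtype=int)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels must align")
    for cls in (0, 1):
        if (labels == cls).sum() < 2:
            raise ValueError("need >= 2 samples per class")
    t_stats, p_values = {}, {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        t, p = stats.ttest_ind(x[labels == 1], x[labels == 0], equal_var=False)
        t_stats[col] = float(t) if np.isfinite(t) else 0.0
        p_values[col] = float(p) if np.isfinite(p) else 1.0
    t_stats = pd.Series(t_stats)
    p_values = pd.Series(p_values)
    survivors = [c for c in features.columns if p_values[c] < alpha]

    warning = None
    if len(survivors) < k:
        warning = (f"only {len(survivors)} features pass the t-test gate "
                   f"(requested k={k})")

    disc = {c: _quartile_bins(features[c].to_numpy(dtype=float), mi_bins)
            for c in survivors}
    relevance = {c: mutual_info_score(labels, disc[c]) for c in survivors}
    selected: list[str] = []
    scores: dict[str, float] = {}
    remaining = list(survivors)
    while remaining and len(selected) < k:
        best_c, best_score = None, -np.inf
        for c in remaining:
            if selected:
                redundancy = np.mean([mutual_info_score(disc[c], disc[s])
                                      for s in selected])
            else:
                redundancy = 0.0
            score = relevance[c] - redundancy
            if score > best_score + 1e-15:
                best_c, best_score = c, score
        selected.append(best_c)
        scores[best_c] = float(best_score)
        remaining.remove(best_c)
    return SelectionResult(selected=selected, t_stats=t_stats, p_values=p_values,
                          mrmr_scores=scores, survivors=survivors, warning=warning)


# ----------------------------------------------------------------------------
# decision-tree classifier
# ----------------------------------------------------------------------------

@dataclass
class TreeModel:
    tree: DecisionTreeClassifier
    feature_names: list[str]


def fit_tree(features: pd.DataFrame, labels, max_depth: int = 5,
             min_samples_leaf: int = 5, seed: int = 0) -> TreeModel:
    """CART tree (Gini) on the selected features; score = leaf class fraction."""
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1 (stumps of depth 0 are not trees)")
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present in training data")
    tree = DecisionTreeClassifier(criterion="gini", max_depth=max_depth,
                                  min_samples_leaf=min_samples_leaf,
                                  random_state=seed)
    tree.fit(features.to_numpy(dtype=float), labels)
    return TreeModel(tree=tree, feature_names=list(features.columns))


def predict_tree(model: TreeModel, features: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    x = features[model.feature_names].to_numpy(dtype=float)
    score = model.tree.predict_proba(x)[:, list(model.tree.classes_).index(1)]
    return (score > 0.5).astype(int), score
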