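"""Attenuation-coefficient (AC) baseline classifier.

The OCT signal below the skin surface decays (to first order) as
``I(z) = I0 * exp(-2 * mu * z)``; fitting ``log I`` against physical depth by
ordinary least squares over a 200-um window below the detected surface yields
a per-A-line attenuation coefficient ``mu = -slope / 2`` (1/mm).  An image is
summarized by the median of its per-A-line coefficients, and a threshold on
that summary — selected on training+validation data only — classifies images
as melanoma or control.

The threshold criterion is Youden's J (sensitivity + specificity - 1); the
direction (whether melanoma raises or lowers the AC) is learned from the data
rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_prep import SurfaceMap

#: floor added to intensities before taking the log
LOG_EPS = 1e-6

DIRECTION_HIGHER = "higher-is-melanoma"
DIRECTION_LOWER = "lower-is-melanoma"


class FitFailure(RuntimeError):
    """No usable A-lines for the attenuation fit."""


@dataclass
class ACResult:
    per_aline_mu: np.ndarray  # (lateral,) 1/mm, NaN where unusable
    image_mu: float  # median of usable per-A-line mu
    fit_r2: np.ndarray  # (lateral,) goodness of fit, NaN where unusable
    n_used: int
    truncated: bool = False  # window exceeded the image depth somewhere


@dataclass
class ACThresholdModel:
    threshold: float
    direction: str  # DIRECTION_HIGHER or DIRECTION_LOWER
    youden_j: float
    degenerate: bool  # True when no separation exists (best J <= 0)
    scale: float  # spread of training mu, used by the logistic score
    chosen_on: str = "train+val"


def fit_attenuation(bscan: np.ndarray, surface: SurfaceMap,
                    axial_um_per_px: float, window_um: float = 200.0,
                    min_window_px: int = 8, min_alines: int = 8,
                    aggregate: str = "median_mu") -> ACResult:
    """Fit mu on every usable A-line over [surface, surface + window_um].

    ``aggregate`` selects the image summary: ``"median_mu"`` (median of
    per-A-line fits, the default) or ``"mean_aline"`` (fit a single line to
    the across-A-line mean intensity profile; lower variance under speckle).
    """
    bscan = np.asarray(bscan, dtype=float)
    depth, lateral = bscan.shape
    window_px = int(round(window_um / axial_um_per_px))
    if window_px < min_window_px:
        raise ValueError(
            f"window of {window_um} um spans only {window_px} px "
            f"(< {min_window_px}); increase the window or the axial sampling")

    mu = np.full(lateral, np.nan)
    r2 = np.full(lateral, np.nan)
    top = surface.surface_index.astype(int)
    truncated = bool(np.any(surface.quality & (top + window_px > depth)))

    def _fit_block(cols: np.ndarray, w_px: int) -> None:
        """Least-squares log-linear fit for columns sharing a window length."""
        if cols.size == 0 or w_px < min_window_px:
            return
        rows = top[cols][None, :] + np.arange(w_px)[:, None]  # (w_px, ncols)
        seg = bscan[rows, cols[None, :]]
        logi = np.log(seg + LOG_EPS)
        z = np.arange(w_px) * axial_um_per_px / 1000.0
        zc = z - z.mean()
        denom = float(np.sum(zc ** 2))
        slope = (zc @ logi) / denom
        mu[cols] = -slope / 2.0
        pred = zc[:, None] * slope[None, :] + logi.mean(axis=0)[None, :]
        ss_res = np.sum((logi - pred) ** 2, axis=0)
        ss_tot = np.sum((logi - logi.mean(axis=0)) ** 2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r2[cols] = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)

    full_cols = np.flatnonzero(surface.quality & (top + window_px <= depth))
    _fit_block(full_cols, window_px)
    # truncated columns share per-length blocks near the bottom edge
    trunc_cols = np.flatnonzero(surface.quality & (top + window_px > depth))
    for w_px in np.unique(depth - top[trunc_cols]):
        _fit_block(trunc_cols[depth - top[trunc_cols] == w_px], int(w_px))

    used = ~np.isnan(mu)
    n_used = int(used.sum())
    if n_used < min_alines:
        raise FitFailure(f"only {n_used} usable A-lines (need >= {min_alines})")
    if aggregate == "median_mu":
        image_mu = float(np.median(mu[used]))
    elif aggregate == "mean_aline":
        if full_cols.size == 0:
            raise FitFailure("no full-window A-lines for the mean-A-line fit")
        rows = top[full_cols][None, :] + np.arange(window_px)[:, None]
        mean_profile = bscan[rows, full_cols[None, :]].mean(axis=1)
        z = np.arange(window_px) * axial_um_per_px / 1000.0
        zc = z - z.mean()
        slope = float(zc @ np.log(mean_profile + LOG_EPS) / np.sum(zc ** 2))
        image_mu = -slope / 2.0
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return ACResult(per_aline_mu=mu, image_mu=image_mu, fit_r2=r2,
                    n_used=n_used, truncated=truncated)


def _confusion_at(values: np.ndarray, labels: np.ndarray, threshold: float,
                  direction: str) -> tuple[float, float]:
    """(sensitivity, specificity) with the strict-inequality tie rule."""
    if direction == DIRECTION_HIGHER:
        pred = values > threshold
    else:
        pred = values < threshold
    pos, neg = labels == 1, labels == 0
    sens = float(pred[pos].mean()) if pos.any() else 0.0
    spec = float((~pred[neg]).mean()) if neg.any() else 0.0
    return sens, spec


def select_threshold(image_mu: np.ndarray, labels: np.ndarray) -> ACThresholdModel:
    """Choose the mu cutoff and direction maximizing Youden's J.

    Candidate cutpoints are the midpoints between consecutive sorted unique
    values (plus sentinels just outside the observed range).  Ties in J are
    broken toward higher sensitivity, then toward the lower threshold.
    """
    image_mu = np.asarray(image_mu, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if image_mu.shape != labels.shape:
        raise ValueError("image_mu and labels must align")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to select a threshold")

    uniq = np.unique(image_mu)
    span = max(uniq[-1] - uniq[0], 1.0)
    candidates = np.concatenate([
        [uniq[0] - 0.5 * span],
        (uniq[:-1] + uniq[1:]) / 2.0,
        [uniq[-1] + 0.5 * span],
    ])
    best = None  # (J, sens, -threshold) lexicographic max
    best_model = None
    for direction in (DIRECTION_HIGHER, DIRECTION_LOWER):
        for thr in candidates:
            sens, spec = _confusion_at(image_mu, labels, thr, direction)
            j = sens + spec - 1.0
            key = (round(j, 12), round(sens, 12), -thr)
            if best is None or key > best:
                best = key
                best_model = (thr, direction, j)
    thr, direction, j = best_model
    scale = float(np.std(image_mu))
    return ACThresholdModel(threshold=float(thr), direction=direction,
                            youden_j=float(j), degenerate=j <= 0.0,
                            scale=scale if scale > 0 else 1.0)


def classify_ac(model: ACThresholdModel, image_mu) -> tuple[np.ndarray, np.ndarray]:
    """Predict melanoma (1) / control (0) and a logistic score for ROC use.

    Values exactly at the threshold classify negative (strict inequality).
    The score is the signed distance to the threshold, in units of the
    training spread, through a logistic squashing — monotone in mu, so ROC
    analysis is unaffected by the squashing.
    """
    image_mu = np.atleast_1d(np.asarray(image_mu, dtype=float))
    signed = image_mu - model.threshold
    if model.direction == DIRECTION_LOWER:
        signed = -signed
    pred = (signed > 0).astype(int)
    score = 1.0 / (1.0 + np.exp(-4.0 * signed / model.scale))
    return pred, score
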