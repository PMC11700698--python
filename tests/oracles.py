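"""Independent brute-force oracles used only by the test suite.

Everything here is written as plain per-element enumeration, deliberately
sharing no code path with the package implementations it checks.
"""

from __future__ import annotations

import math

import numpy as np


# -- radiomics: naive per-pixel feature implementations -----------------------

def naive_quantize(values, bins):
    lo, hi = min(values), max(values)
    if hi <= lo:
        return [0 for _ in values]
    out = []
    for v in values:
        level = int(math.floor((v - lo) / (hi - lo) * bins))
        out.append(min(level, bins - 1))
    return out


def naive_glcm(image, mask, bins, offsets):
    """Symmetric GLCM by explicit pair enumeration, averaged over offsets."""
    h, w = len(image), len(image[0])
    vals = [image[r][c] for r in range(h) for c in range(w) if mask[r][c]]
    qlut = {}
    q = naive_quantize(vals, bins)
    k = 0
    qimg = [[0] * w for _ in range(h)]
    for r in range(h):
        for c in range(w):
            if mask[r][c]:
                qimg[r][c] = q[k]
                k += 1
    mats = []
    for dr, dc in offsets:
        mat = [[0.0] * bins for _ in range(bins)]
        count = 0
        for r in range(h):
            for c in range(w):
                r2, c2 = r + dr, c + dc
                if 0 <= r2 < h and 0 <= c2 < w and mask[r][c] and mask[r2][c2]:
                    a, b = qimg[r][c], qimg[r2][c2]
                    mat[a][b] += 1
                    mat[b][a] += 1
                    count += 2
        if count:
            mats.append([[x / count for x in row] for row in mat])
    if not mats:
        mat = [[0.0] * bins for _ in range(bins)]
        mat[0][0] = 1.0
        return mat
    out = [[0.0] * bins for _ in range(bins)]
    for m in mats:
        for i in range(bins):
            for j in range(bins):
                out[i][j] += m[i][j] / len(mats)
    return out


def naive_features(image, mask, bins=32,
                   offsets=((0, 1), (-1, 1), (-1, 0), (-1, -1))):
    """The five headline features by direct enumeration."""
    h, w = len(image), len(image[0])
    vals = sorted(image[r][c] for r in range(h) for c in range(w) if mask[r][c])
    n = len(vals)
    mean = sum(vals) / n
    var = sum((v - mean) ** 2 for v in vals) / n
    if var > 0:
        kurt = (sum((v - mean) ** 4 for v in vals) / n) / var ** 2
    else:
        kurt = 0.0

    def pct(p):
        # linear interpolation, matching numpy's default
        idx = p / 100.0 * (n - 1)
        lo = int(math.floor(idx))
        hi = min(lo + 1, n - 1)
        return vals[lo] + (vals[hi] - vals[lo]) * (idx - lo)

    iqr = pct(75) - pct(25)
    p10, p90 = pct(10), pct(90)
    sub = [v for v in vals if p10 <= v <= p90]
    sub_mean = sum(sub) / len(sub)
    rmad = sum(abs(v - sub_mean) for v in sub) / len(sub)

    p = naive_glcm(image, mask, bins, offsets)
    energy = sum(x * x for row in p for x in row)
    maxprob = max(x for row in p for x in row)
    return {
        "kurtosis": kurt,
        "interquartile_range": iqr,
        "robust_mean_absolute_deviation": rmad,
        "glcm_joint_energy": energy,
        "glcm_maximum_probability": maxprob,
    }


# -- attenuation: exhaustive Youden threshold search --------------------------

def brute_force_youden(values, labels):
    """Best (J, direction, threshold) by scanning every candidate cutpoint."""
    values = list(map(float, values))
    uniq = sorted(set(values))
    span = max(uniq[-1] - uniq[0], 1.0)
    cands = [uniq[0] - 0.5 * span]
    cands += [(a + b) / 2.0 for a, b in zip(uniq, uniq[1:])]
    cands += [uniq[-1] + 0.5 * span]
    best = None
    for direction in ("higher-is-melanoma", "lower-is-melanoma"):
        for thr in cands:
            tp = fp = tn = fn = 0
            for v, y in zip(values, labels):
                pred = v > thr if direction == "higher-is-melanoma" else v < thr
                if pred and y == 1:
                    tp += 1
                elif pred and y == 0:
                    fp += 1
                elif not pred and y == 0:
                    tn += 1
                else:
                    fn += 1
            sens = tp / (tp + fn) if tp + fn else 0.0
            spec = tn / (tn + fp) if tn + fp else 0.0
            j = sens + spec - 1.0
            key = (round(j, 12), round(sens, 12), -thr)
            if best is None or key > best[0]:
                best = (key, j, direction, thr)
    return best[1], best[2], best[3]


# -- mRmR: brute-force MID scoring --------------------------------------------

def discrete_mi(x, y):
    """Mutual information (nats) of two discrete sequences, by counting."""
    n = len(x)
    from collections import Counter
    cx, cy, cxy = Counter(x), Counter(y), Counter(zip(x, y))
    mi = 0.0
    for (a, b), nab in cxy.items():
        pab = nab / n
        mi += pab * math.log(pab / (cx[a] / n * cy[b] / n))
    return mi


def brute_force_mid_order(disc_features, labels, k):
    """Greedy MID selection by direct score evaluation at every step."""
    names = list(disc_features)
    selected = []
    while names and len(selected) < k:
        best_name, best_score = None, -float("inf")
        for name in names:
            rel = discrete_mi(disc_features[name], labels)
            if selected:
                red = sum(discrete_mi(disc_features[name], disc_features[s])
                          for s in selected) / len(selected)
            else:
                red = 0.0
            score = rel - red
            if score > best_score + 1e-15:
                best_name, best_score = name, score
        selected.append(best_name)
        names.remove(best_name)
    return selected


# -- relative loss and AUC ----------------------------------------------------

def brute_force_relative_loss(pairs):
    """Per-pair ReLU evaluation of the temporal ranking penalty."""
    total = 0.0
    for y1, y2 in pairs:
        d = y1 - y2
        total += d if d > 0 else 0.0
    return total / len(pairs)


def mann_whitney_auc(scores, labels):
    """AUC as the normalized pairwise-comparison count (ties count 1/2)."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))
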