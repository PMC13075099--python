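"""Independent reference implementations used only as test oracles.

Each function re-implements an operation in the most transparent way
possible (explicit loops, scipy primitives) so the package's optimized
paths can be checked against it.
"""
from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline


def find_extrema_ref(x: np.ndarray):
    """Strict interior maxima/minima, mirroring the sifting kernel."""
    mx, mn = [], []
    for i in range(1, x.size - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            mx.append(i)
        elif x[i] < x[i - 1] and x[i] < x[i + 1]:
            mn.append(i)
    return np.array(mx, dtype=int), np.array(mn, dtype=int)


def envelope_ref(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Natural cubic-spline envelope with two mirrored extrema per end."""
    n = x.size
    t = np.concatenate(
        [
            [-idx[1], -idx[0]],
            idx,
            [2 * (n - 1) - idx[-1], 2 * (n - 1) - idx[-2]],
        ]
    ).astype(float)
    v = np.concatenate([[x[idx[1]], x[idx[0]]], x[idx], [x[idx[-1]], x[idx[-2]]]])
    return CubicSpline(t, v, bc_type="natural")(np.arange(n, dtype=float))


def emd_ref(x: np.ndarray, max_imfs: int = 8, sd_thresh: float = 0.2, max_sift: int = 50):
    """Reference sifting: same spline, mirroring, and Cauchy stop rule."""
    r = x.astype(float).copy()
    imfs = []
    while len(imfs) < max_imfs:
        mx, mn = find_extrema_ref(r)
        if mx.size + mn.size < 3:
            break
        h = r.copy()
        for _ in range(max_sift):
            hmx, hmn = find_extrema_ref(h)
            if hmx.size < 2 or hmn.size < 2:
                break
            m = 0.5 * (envelope_ref(h, hmx) + envelope_ref(h, hmn))
            prev = float(np.sum(h * h))
            h = h - m
            if prev <= 0 or float(np.sum(m * m)) / prev < sd_thresh:
                break
        imfs.append(h)
        r = r - h
    return imfs, r


def auc_ref(labels, scores) -> float:
    """Brute-force pairwise AUC with ties counted one half."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        return 0.5
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


def label_imf_ref(imf, peaks, half_window=50, statistic="max") -> int:
    """Naive re-implementation of the IMF labeling rule."""
    imf = np.asarray(imf, dtype=float)
    peaks = list(peaks)
    if not peaks or imf.size == 0:
        return 0
    p_global = imf.max() - imf.min()
    if p_global == 0:
        return 0
    sigma = imf.std()
    locals_ = []
    for k in peaks:
        window = imf[max(0, k - half_window) : min(imf.size, k + half_window + 1)]
        locals_.append(window.max() - window.min() if window.size else 0.0)
    m = float(np.max(locals_)) if statistic == "max" else float(np.median(locals_))
    return 1 if (m > 1.4 * sigma and m > 0.75 * p_global) else 0


def match_rpeaks_ref(detected, reference, tol: float):
    """Exhaustive best one-to-one matching (for short beat lists)."""
    det = list(detected)
    ref = list(reference)

    def rec(i, used):
        if i == len(ref):
            return 0
        best = rec(i + 1, used)
        for j in range(len(det)):
            if j not in used and abs(det[j] - ref[i]) <= tol:
                best = max(best, 1 + rec(i + 1, used | {j}))
        return best

    best_tp = rec(0, frozenset())
    fp = len(det) - best_tp
    fn = len(ref) - best_tp
    precision = best_tp / len(det) if det else 0.0
    recall = best_tp / len(ref) if ref else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return best_tp, fp, fn, precision, recall, f1
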