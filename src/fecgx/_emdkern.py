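"""Compiled EMD sifting kernel.

Hot path of the decomposition: strict interior extrema detection,
mirror extension of two extrema per end, natural cubic-spline envelopes
(Thomas-algorithm tridiagonal solve), Cauchy-SD sifting stop. Kept in a
separate module so the pure-Python reference used in tests can mirror
the algorithm line by line.
"""
from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["emd_core"]


@njit(cache=True)
def _find_extrema(x):
    n = x.size
    mx = np.empty(n, np.int64)
    mn = np.empty(n, np.int64)
    imx = 0
    imn = 0
    for i in range(1, n - 1):
        if x[i] > x[i - 1] and x[i] > x[i + 1]:
            mx[imx] = i
            imx += 1
        elif x[i] < x[i - 1] and x[i] < x[i + 1]:
            mn[imn] = i
            imn += 1
    return mx[:imx], mn[:imn]


@njit(cache=True)
def _natural_spline_eval(t, v, n_out):
    """Natural cubic spline through (t, v), evaluated at 0..n_out-1."""
    m = t.size
    out = np.empty(n_out)
    if m == 2:
        slope = (v[1] - v[0]) / (t[1] - t[0])
        for s in range(n_out):
            out[s] = v[0] + slope * (s - t[0])
        return out
    # second derivatives M: natural boundary (M[0] = M[m-1] = 0)
    h = np.empty(m - 1)
    for i in range(m - 1):
        h[i] = t[i + 1] - t[i]
    a = np.zeros(m)
    b = np.ones(m)
    c = np.zeros(m)
    d = np.zeros(m)
    for i in range(1, m - 1):
        a[i] = h[i - 1]
        b[i] = 2.0 * (h[i - 1] + h[i])
        c[i] = h[i]
        d[i] = 6.0 * ((v[i + 1] - v[i]) / h[i] - (v[i] - v[i - 1]) / h[i - 1])
    # Thomas solve
    for i in range(1, m):
        w = a[i] / b[i - 1]
        b[i] -= w * c[i - 1]
        d[i] -= w * d[i - 1]
    M = np.zeros(m)
    M[m - 1] = d[m - 1] / b[m - 1]
    for i in range(m - 2, -1, -1):
        M[i] = (d[i] - c[i] * M[i + 1]) / b[i]
    # evaluate
    seg = 0
    for s in range(n_out):
        x = float(s)
        while seg < m - 2 and x > t[seg + 1]:
            seg += 1
        hs = h[seg]
        A = (t[seg + 1] - x) / hs
        B = (x - t[seg]) / hs
        out[s] = (
            A * v[seg]
            + B * v[seg + 1]
            + ((A**3 - A) * M[seg] + (B**3 - B) * M[seg + 1]) * hs * hs / 6.0
        )
    return out


@njit(cache=True)
def _envelope(x, idx):
    """Spline envelope through extrema ``idx`` with 2-point mirroring."""
    n = x.size
    k = idx.size
    t = np.empty(k + 4)
    v = np.empty(k + 4)
    # mirror two extrema about each end (strict extrema are interior,
    # so reflected knots never collide with sample 0 or n-1)
    t[0] = -float(idx[1])
    v[0] = x[idx[1]]
    t[1] = -float(idx[0])
    v[1] = x[idx[0]]
    for j in range(k):
        t[2 + j] = float(idx[j])
        v[2 + j] = x[idx[j]]
    t[k + 2] = 2.0 * (n - 1) - float(idx[k - 1])
    v[k + 2] = x[idx[k - 1]]
    t[k + 3] = 2.0 * (n - 1) - float(idx[k - 2])
    v[k + 3] = x[idx[k - 2]]
    return _natural_spline_eval(t, v, n)


@njit(cache=True)
def emd_core(x, max_imfs, sd_thresh, max_sift):
    """Plain EMD: returns (imfs array [k, n], residual)."""
    n = x.size
    imfs = np.zeros((max_imfs, n))
    r = x.copy()
    k = 0
    while k < max_imfs:
        mx, mn = _find_extrema(r)
        if mx.size + mn.size < 3:
            break
        h = r.copy()
        for _ in range(max_sift):
            hmx, hmn = _find_extrema(h)
            if hmx.size < 2 or hmn.size < 2:
                break
            upper = _envelope(h, hmx)
            lower = _envelope(h, hmn)
            prev_energy = 0.0
            diff_energy = 0.0
            for i in range(n):
                m = 0.5 * (upper[i] + lower[i])
                prev_energy += h[i] * h[i]
                diff_energy += m * m
                h[i] = h[i] - m
            if prev_energy <= 0.0:
                break
            if diff_energy / prev_energy < sd_thresh:
                break
        for i in range(n):
            imfs[k, i] = h[i]
            r[i] = r[i] - h[i]
        k += 1
    return imfs[:k], r
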