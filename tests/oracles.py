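"""Independent brute-force reference implementations used only by tests.

Everything here is written as plain loops over scalars, deliberately sharing
no code path with the package, so agreement is evidence of correctness
rather than tautology.
"""

from __future__ import annotations

import math

import numpy as np


def lstm_step_loops(x, h_prev, c_prev, tf, ti, to, tc, bf, bi, bo, bc):
    """Scalar-loop LSTM cell update: inputs (B, I), states (B, H)."""
    B, H = h_prev.shape
    I = x.shape[1]
    h_out = np.zeros((B, H))
    c_out = np.zeros((B, H))
    for b in range(B):
        z = list(h_prev[b]) + list(x[b])
        for j in range(H):
            f = i = o = c = 0.0
            for k in range(H + I):
                f += z[k] * tf[k, j]
                i += z[k] * ti[k, j]
                o += z[k] * to[k, j]
                c += z[k] * tc[k, j]
            fg = 1.0 / (1.0 + math.exp(-(f + bf[j])))
            ig = 1.0 / (1.0 + math.exp(-(i + bi[j])))
            og = 1.0 / (1.0 + math.exp(-(o + bo[j])))
            ct = fg * c_prev[b, j] + ig * math.tanh(c + bc[j])
            c_out[b, j] = ct
            h_out[b, j] = og * math.tanh(ct)
    return h_out, c_out


def attention_loops(y):
    """Two-loop softmax self-attention over a (T, d) sequence."""
    T, d = y.shape
    out = np.zeros_like(y)
    for t in range(T):
        scores = [sum(y[t, k] * y[tp, k] for k in range(d)) for tp in range(T)]
        m = max(scores)
        exps = [math.exp(s - m) for s in scores]
        tot = sum(exps)
        for tp in range(T):
            w = exps[tp] / tot
            for k in range(d):
                out[t, k] += w * y[tp, k]
    return out


def conv1d_relu_loops(x, kernel3d, bias):
    """Nested-loop valid 1D convolution + ReLU.

    x: (T, C); kernel3d: (m, C, F); bias: (F,). Returns (T - m + 1, F).
    """
    T, C = x.shape
    m, _, F = kernel3d.shape
    out = np.zeros((T - m + 1, F))
    for i in range(T - m + 1):
        for f in range(F):
            acc = bias[f]
            for k in range(m):
                for c in range(C):
                    acc += x[i + k, c] * kernel3d[k, c, f]
            out[i, f] = max(0.0, acc)
    return out


# ---------------------------------------------------------------------------
# Parkes type-2 boundary-band classifier (independent of the polygon route)
# ---------------------------------------------------------------------------

# boundary polylines as (x, y) vertex lists; *_V marks a leading vertical
# segment whose x bound replaces interpolation left of it
_AB_UPPER = [(0, 50), (30, 50), (230, 330), (440, 550)]
_BC_UPPER = [(0, 60), (30, 60), (280, 550)]
_CD_UPPER = [(0, 80), (25, 80), (35, 90), (125, 550)]
_DE_UPPER = [(0, 200), (35, 200), (50, 550)]
_AB_LOWER = [(50, 30), (90, 80), (330, 230), (550, 450)]   # vertical x=50 below y=30
_BC_LOWER = [(90, 0), (260, 130), (550, 250)]
_CD_LOWER = [(250, 40), (410, 110), (550, 160)]            # vertical x=250 below y=40


def _interp(poly, x):
    xs = [p[0] for p in poly]
    ys = [p[1] for p in poly]
    for i in range(len(xs) - 1):
        if xs[i] <= x <= xs[i + 1]:
            if xs[i + 1] == xs[i]:
                return ys[i]
            frac = (x - xs[i]) / (xs[i + 1] - xs[i])
            return ys[i] + frac * (ys[i + 1] - ys[i])
    return None


def _above(poly, x, y):
    f = _interp(poly, x)
    return f is not None and y > f


def _below(poly, x, y, x_min=None):
    if x_min is not None and x <= x_min:
        return False
    f = _interp(poly, x)
    if f is None and x_min is not None and x > poly[-1][0]:
        return False
    return f is not None and y < f


def parkes_zone_bands(x: float, y: float) -> str:
    """Classify a (reference, predicted) point by boundary bands."""
    if y >= x:
        if _above(_DE_UPPER, x, y):
            return "E"
        if _above(_CD_UPPER, x, y):
            return "D"
        if _above(_BC_UPPER, x, y):
            return "C"
        if _above(_AB_UPPER, x, y):
            return "B"
        return "A"
    if _below(_CD_LOWER, x, y, x_min=250):
        return "D"
    if _below(_BC_LOWER, x, y):
        return "C"
    if _below(_AB_LOWER, x, y, x_min=50):
        return "B"
    return "A"
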