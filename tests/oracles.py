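"""Independent brute-force oracles used to pin the fast implementations.

Everything here is written naively (per-pixel Python loops, explicit
arithmetic) and shares only the documented conventions with the
library: neighbor geometry starting at angle 0 going counter-clockwise,
bilinear interpolation with near-integer snapping, the 1e-6 comparison
tolerance, ascending-code uniform bins with a trailing pooled bin.
"""

from __future__ import annotations

import math

import numpy as np


def _bilinear(g: np.ndarray, y: float, x: float) -> float:
    y0, x0 = math.floor(y), math.floor(x)
    wy, wx = y - y0, x - x0
    if wy < 1e-9:
        wy = 0.0
    elif wy > 1 - 1e-9:
        y0, wy = y0 + 1, 0.0
    if wx < 1e-9:
        wx = 0.0
    elif wx > 1 - 1e-9:
        x0, wx = x0 + 1, 0.0
    val = 0.0
    for yy, py in ((y0, 1 - wy), (y0 + 1, wy)):
        if py == 0.0:
            continue
        for xx, px in ((x0, 1 - wx), (x0 + 1, wx)):
            if px == 0.0:
                continue
            val += py * px * g[yy, xx]
    return val


def _circular_transitions(code: int, p: int) -> int:
    bits = [(code >> k) & 1 for k in range(p)]
    return sum(bits[k] != bits[(k + 1) % p] for k in range(p))


def oracle_ulbp_histogram(
    patch: np.ndarray, radius: int, p: int = 8, strict_gt: bool = False
) -> np.ndarray:
    """Per-pixel brute-force uniform-LBP histogram."""
    g = np.asarray(patch, dtype=float)
    h, w = g.shape
    uniform_codes = [c for c in range(2**p) if _circular_transitions(c, p) <= 2]
    bin_of = {c: i for i, c in enumerate(uniform_codes)}
    n_bins = p * (p - 1) + 3
    hist = np.zeros(n_bins)
    count = 0
    for i in range(radius, h - radius):
        for j in range(radius, w - radius):
            code = 0
            for k in range(p):
                ang = 2.0 * math.pi * k / p
                dy, dx = -radius * math.sin(ang), radius * math.cos(ang)
                if abs(dy - round(dy)) < 1e-9:
                    dy = round(dy)
                if abs(dx - round(dx)) < 1e-9:
                    dx = round(dx)
                v = _bilinear(g, i + dy, j + dx)
                if strict_gt:
                    bit = v > g[i, j] + 1e-6
                else:
                    bit = v >= g[i, j] - 1e-6
                if bit:
                    code |= 1 << k
            hist[bin_of.get(code, n_bins - 1)] += 1
            count += 1
    return hist / count


def oracle_dmw_weights(features: np.ndarray) -> np.ndarray:
    """Loop-based evaluation of the mean-distance reciprocal weights."""
    feats = np.asarray(features, dtype=float)
    m = feats.shape[0]
    if m == 1:
        return np.array([1.0])
    da = []
    for k in range(m):
        total = 0.0
        for i in range(m):
            total += math.dist(feats[k], feats[i])
        da.append(total / (m - 1))
    sd = [1.0 / v for v in da]
    s = sum(sd)
    return np.array([v / s for v in sd])
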