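"""Handcrafted subpatch descriptors and parent-patch aggregation.

Three feature families are computed per subpatch and pooled to the
parent patch:

* ``r_LBP`` — uniform local binary pattern histograms on the 8-bit
  blue-ratio image, radii 1 and 2 with p=8 samples: 59 bins per radius,
  118 dims per subpatch, 472 per parent after aggregation.
* ``r_sta`` — 9 order/moment statistics of the gray values: 36 per
  parent.
* ``r_Lab`` — 85-bin histograms of the Lab a and b channels: 170 per
  subpatch, 680 per parent.

Parent aggregation concatenates the per-dimension mean, population
standard deviation and the 10th/90th percentiles of the subpatch
vectors, in that block order.

ULBP conventions (fixed so results are reproducible): neighbors sampled
counter-clockwise from angle 0 at ``(dy, dx) = (-r sin, r cos)`` with
bilinear interpolation; a neighbor contributes bit 1 when its value is
>= the center value minus 1e-6 (``strict_gt=True`` switches to > plus
1e-6, following the literal "greater than" reading); bit k has weight
2^k; uniform codes (<= 2 circular transitions) are binned in ascending
code order with a single trailing bin pooling all non-uniform codes;
histograms are normalized to sum 1 over valid interior pixels.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .config import LBPConfig

_EPS_CMP = 1e-6  # tolerance absorbing bilinear round-off in the bit comparison


@lru_cache(maxsize=None)
def uniform_code_table(p: int) -> np.ndarray:
    """Map each p-bit LBP code to its histogram bin.

    Uniform codes (at most two circular 0/1 transitions) occupy bins
    0 .. p(p-1)+1 in ascending code order; every non-uniform code maps
    to the last bin, index p(p-1)+2.
    """
    n_bins = p * (p - 1) + 3
    table = np.full(2**p, n_bins - 1, dtype=np.int64)
    idx = 0
    for code in range(2**p):
        bits = [(code >> k) & 1 for k in range(p)]
        transitions = sum(bits[k] != bits[(k + 1) % p] for k in range(p))
        if transitions <= 2:
            table[code] = idx
            idx += 1
    assert idx == p * (p - 1) + 2
    return table


@lru_cache(maxsize=None)
def _neighbor_offsets(p: int, radius: int) -> tuple[tuple[float, float], ...]:
    angles = 2.0 * np.pi * np.arange(p) / p
    dy = -radius * np.sin(angles)
    dx = radius * np.cos(angles)
    # snap near-integer coordinates so exact lattice neighbors skip interpolation
    dy = np.where(np.abs(dy - np.rint(dy)) < 1e-9, np.rint(dy), dy)
    dx = np.where(np.abs(dx - np.rint(dx)) < 1e-9, np.rint(dx), dx)
    return tuple((float(a), float(b)) for a, b in zip(dy, dx))


def _sample_offset(gray: np.ndarray, dy: float, dx: float, radius: int) -> np.ndarray:
    """Bilinearly sample ``gray`` at offset (dy, dx) for all interior pixels."""
    h, w = gray.shape
    ih, iw = h - 2 * radius, w - 2 * radius
    fy, fx = radius + dy, radius + dx
    y0, x0 = int(np.floor(fy)), int(np.floor(fx))
    wy, wx = fy - y0, fx - x0
    if wy < 1e-9:
        wy = 0.0
    elif wy > 1 - 1e-9:
        y0, wy = y0 + 1, 0.0
    if wx < 1e-9:
        wx = 0.0
    elif wx > 1 - 1e-9:
        x0, wx = x0 + 1, 0.0
    out = np.zeros((ih, iw))
    for yy, py in ((y0, 1.0 - wy), (y0 + 1, wy)):
        if py == 0.0:
            continue
        for xx, px in ((x0, 1.0 - wx), (x0 + 1, wx)):
            if px == 0.0:
                continue
            out += (py * px) * gray[yy : yy + ih, xx : xx + iw]
    return out


def ulbp_codes(
    gray_patch: np.ndarray, radius: int, p: int = 8, strict_gt: bool = False
) -> np.ndarray:
    """Uniform-ready LBP code image over the valid interior.

    Returns an ``(H-2r) x (W-2r)`` integer array of raw p-bit codes for
    every pixel whose full circular neighborhood fits in the patch.
    """
    gray = np.asarray(gray_patch, dtype=np.float64)
    if gray.ndim != 2:
        raise ValueError(f"expected a 2-D gray patch, got shape {gray.shape}")
    h, w = gray.shape
    if min(h, w) <= 2 * radius:
        raise ValueError(f"patch of shape {gray.shape} too small for radius {radius}")
    center = gray[radius : h - radius, radius : w - radius]
    codes = np.zeros(center.shape, dtype=np.int64)
    for k, (dy, dx) in enumerate(_neighbor_offsets(p, radius)):
        sampled = _sample_offset(gray, dy, dx, radius)
        if strict_gt:
            bit = sampled > center + _EPS_CMP
        else:
            bit = sampled >= center - _EPS_CMP
        codes |= bit.astype(np.int64) << k
    return codes


def histogram_from_codes(codes: np.ndarray, p: int = 8) -> np.ndarray:
    """Normalized uniform-pattern histogram of an LBP code array."""
    table = uniform_code_table(p)
    n_bins = p * (p - 1) + 3
    binned = table[np.asarray(codes).ravel()]
    hist = np.bincount(binned, minlength=n_bins).astype(np.float64)
    total = hist.sum()
    if total > 0:
        hist /= total
    return hist


def ulbp_histogram(
    gray_patch: np.ndarray, radius: int, p: int = 8, strict_gt: bool = False
) -> np.ndarray:
    """Normalized ULBP histogram of one gray patch (length p(p-1)+3)."""
    codes = ulbp_codes(gray_patch, radius, p=p, strict_gt=strict_gt)
    return histogram_from_codes(codes, p=p)


def subpatch_lbp_features(gray_patch: np.ndarray, cfg: LBPConfig) -> np.ndarray:
    """Concatenated ULBP histograms over ``cfg.radii`` (118 dims by default)."""
    return np.concatenate(
        [
            ulbp_histogram(gray_patch, radius, p=cfg.p, strict_gt=cfg.strict_gt)
            for radius in cfg.radii
        ]
    )


def gray_stats(gray_patch: np.ndarray) -> np.ndarray:
    """9 gray-level statistics in the fixed order
    (max, min, sum, mean, std, median, Q1, Q3, IQR).

    Standard deviation is the population form; quartiles use linear
    interpolation between order statistics.
    """
    v = np.asarray(gray_patch, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("empty patch")
    q1, q3 = np.percentile(v, [25.0, 75.0])
    return np.array(
        [v.max(), v.min(), v.sum(), v.mean(), v.std(), np.median(v), q1, q3, q3 - q1]
    )


def lab_color_histogram(lab_patch: np.ndarray, bins: int = 85) -> np.ndarray:
    """Concatenated a- then b-channel histograms over [-128, 127].

    Each channel is clipped to [-128, 127], binned into ``bins``
    equal-width bins and normalized to sum 1; default length 170.
    """
    lab = np.asarray(lab_patch, dtype=np.float64)
    if lab.ndim != 3 or lab.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 Lab patch, got shape {lab.shape}")
    out = []
    for ch in (1, 2):
        vals = np.clip(lab[..., ch].ravel(), -128.0, 127.0)
        hist, _ = np.histogram(vals, bins=bins, range=(-128.0, 127.0))
        out.append(hist / vals.size)
    return np.concatenate(out)


def aggregate_parent(sub_vectors: list[np.ndarray] | np.ndarray) -> np.ndarray:
    """Pool subpatch vectors to one parent vector.

    Concatenates the per-dimension (mean, population std, 10th
    percentile, 90th percentile) blocks, each of the subpatch length n,
    giving 4n dims.
    """
    if len(sub_vectors) == 0:
        raise ValueError("aggregate_parent needs at least one subpatch vector")
    lengths = {np.asarray(v).shape for v in sub_vectors}
    if len(lengths) != 1:
        raise ValueError(f"ragged subpatch vectors: shapes {sorted(lengths)}")
    mat = np.asarray(sub_vectors, dtype=np.float64)
    p10, p90 = np.percentile(mat, [10.0, 90.0], axis=0)
    return np.concatenate([mat.mean(axis=0), mat.std(axis=0), p10, p90])
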