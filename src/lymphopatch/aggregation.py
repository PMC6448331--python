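"""Patch-to-image score aggregation: MV, MS, DMW, and path fusion.

Three strategies turn the m per-patch class-probability vectors of one
image into an image-level prediction:

* majority voting (MV) over patch labels;
* mean score (MS), the arithmetic mean of patch score vectors;
* distance matrix weighting (DMW): patches whose feature vectors sit
  close to the rest of the image's patches get larger weights. With
  pairwise Euclidean distances d_ij, each patch k receives

      da_k = (1 / (m - 1)) * sum_i d_ki        (mean distance, diagonal
                                                d_kk = 0 included)
      Sd_k = 1 / da_k                          (closeness score)
      w_k  = Sd_k / sum_i Sd_i                 (normalized weight)

  and the image score is the weighted sum S_I = sum_k w_k s_k.

Five combination modes mix the handcrafted paths (F1, F2), the deep
path, and the strategies:
C1 = F1 + DMW; C2 = F2 + MS; C3 = patch-level fusion
w_P*S_F1 + (1-w_P)*S_F2 followed by DMW; C4 = deep + DMW;
C5 = image-level fusion w_I*C3 + (1-w_I)*C4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .config import FusionConfig, N_CLASSES


@dataclass
class PatchScores:
    """Per-parent-patch class scores of one image for one path.

    ``scores`` is (m, 3) in grid row-major order; ``features`` is the
    (m, d) matrix of the same patches' feature vectors, required for
    DMW.
    """

    scores: np.ndarray
    features: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 2 or self.scores.shape[1] != N_CLASSES:
            raise ValueError(f"scores must be (m, {N_CLASSES}), got {self.scores.shape}")
        if self.scores.shape[0] < 1:
            raise ValueError("need at least one patch")
        if self.features is not None:
            self.features = np.asarray(self.features, dtype=np.float64)
            if self.features.shape[0] != self.scores.shape[0]:
                raise ValueError("features and scores disagree on the patch count m")

    @property
    def m(self) -> int:
        return self.scores.shape[0]


def majority_vote(patch_labels: Sequence[int]) -> int:
    """Most frequent patch class index; ties go to the lowest index."""
    labels = np.asarray(patch_labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("majority_vote needs at least one patch label")
    counts = np.bincount(labels, minlength=N_CLASSES)
    return int(np.argmax(counts))


def mean_score(scores: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the m patch score vectors (stays on the simplex)."""
    arr = np.asarray(scores, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError(f"expected a non-empty (m, k) score array, got shape {arr.shape}")
    return arr.mean(axis=0)


def _standardize(features: np.ndarray) -> np.ndarray:
    mu = features.mean(axis=0)
    sd = features.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (features - mu) / sd


def dmw_weights(features: np.ndarray, standardize: bool = False) -> np.ndarray:
    """Distance-matrix weights for the m patches of one image.

    ``standardize=True`` z-scores each feature dimension over the
    image's patches before the Euclidean distances so heterogeneous
    feature scales do not dominate; the default is the raw form.

    Degenerate cases: m=1 returns [1.0]; identical patches (all
    distances zero) return uniform weights; a zero mean distance is
    clamped to 1e-12 times the largest pairwise distance.
    """
    feats = np.asarray(features, dtype=np.float64)
    if feats.ndim == 1:
        feats = feats[:, None]
    if feats.ndim != 2:
        raise ValueError(f"expected an (m, d) feature array, got shape {feats.shape}")
    m = feats.shape[0]
    if m == 1:
        return np.array([1.0])
    if standardize:
        feats = _standardize(feats)
    dmat = squareform(pdist(feats, metric="euclidean"))
    d_max = dmat.max()
    if d_max == 0.0:
        return np.full(m, 1.0 / m)
    da = dmat.sum(axis=1) / (m - 1)
    da = np.maximum(da, 1e-12 * d_max)
    sd = 1.0 / da
    return sd / sd.sum()


def dmw_image_score(scores: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted sum S_I = sum_i w_i * s_i of the patch scores."""
    s = np.asarray(scores, dtype=np.float64)
    w = np.asarray(weights, dtype=np.float64)
    if s.shape[0] != w.shape[0]:
        raise ValueError(f"{w.shape[0]} weights for {s.shape[0]} patches")
    return w @ s


def fuse_patch_scores(s1: np.ndarray, s2: np.ndarray, w_p: float) -> np.ndarray:
    """Patch-level convex fusion ``w_P * S1 + (1 - w_P) * S2``."""
    a = np.asarray(s1, dtype=np.float64)
    b = np.asarray(s2, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"mismatched patch score sets: {a.shape} vs {b.shape}")
    return w_p * a + (1.0 - w_p) * b


def fuse_image_scores(s_i3: np.ndarray, s_i4: np.ndarray, w_i: float) -> np.ndarray:
    """Image-level convex fusion ``w_I * S_I3 + (1 - w_I) * S_I4``."""
    return w_i * np.asarray(s_i3, dtype=np.float64) + (1.0 - w_i) * np.asarray(
        s_i4, dtype=np.float64
    )


def _dmw_over(path: PatchScores, standardize: bool) -> np.ndarray:
    if path.features is None:
        raise ValueError("DMW needs per-patch feature vectors on this path")
    w = dmw_weights(path.features, standardize=standardize)
    return dmw_image_score(path.scores, w)


def run_combination_mode(
    mode: str, paths: Mapping[str, PatchScores], cfg: FusionConfig
) -> np.ndarray:
    """Image-level score for one image under combination mode C1..C5.

    ``paths`` maps path names to per-patch results: C1 needs "F1", C2
    needs "F2", C3 needs both (DMW uses the F2 features), C4 needs
    "deep", C5 needs everything C3 and C4 need.
    """

    def need(name: str) -> PatchScores:
        if name not in paths:
            raise KeyError(f"combination mode {mode} requires the {name!r} path")
        return paths[name]

    std = cfg.dmw_standardize
    if mode == "C1":
        return _dmw_over(need("F1"), std)
    if mode == "C2":
        return mean_score(need("F2").scores)
    if mode == "C3":
        p1, p2 = need("F1"), need("F2")
        fused = fuse_patch_scores(p1.scores, p2.scores, cfg.w_P)
        if p2.features is None:
            raise ValueError("mode C3 needs feature vectors on the F2 path for DMW")
        w = dmw_weights(p2.features, standardize=std)
        return dmw_image_score(fused, w)
    if mode == "C4":
        return _dmw_over(need("deep"), std)
    if mode == "C5":
        s_i3 = run_combination_mode("C3", paths, cfg)
        s_i4 = run_combination_mode("C4", paths, cfg)
        return fuse_image_scores(s_i3, s_i4, cfg.w_I)
    raise ValueError(f"unknown combination mode {mode!r}")
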