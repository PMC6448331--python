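"""Pluggable deep-feature path: patch embeddings plus a softmax head.

The contract is a fixed-width embedding per RGB patch followed by a
multinomial logistic ("softmax") scorer. Two backends exist:

* ``mock`` — a deterministic stand-in: each patch is mean-pooled to a
  16x16x3 thumbnail and projected by a fixed seeded Gaussian matrix to
  ``feature_dim`` dims. Identical patches give identical vectors; any
  pixel change propagates through the dense projection. This keeps the
  whole C4/C5 machinery runnable and testable offline.
* ``pretrained`` — Inception v3 pre-logit pooled activations (2048-d),
  available only when torchvision and its weights are installed.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from skimage.transform import resize
from sklearn.linear_model import SGDClassifier
from sklearn.preprocessing import StandardScaler

from .config import CLASSES, DeepConfig, N_CLASSES

_MOCK_THUMB = 16
_MOCK_SEED = 1_315_423_911  # fixed: the projection is part of the backend identity


@lru_cache(maxsize=4)
def _mock_projection(feature_dim: int) -> np.ndarray:
    rng = np.random.default_rng(_MOCK_SEED)
    n_in = _MOCK_THUMB * _MOCK_THUMB * 3
    return rng.standard_normal((feature_dim, n_in)) / np.sqrt(n_in)


def _mock_embed(patch: np.ndarray, feature_dim: int) -> np.ndarray:
    thumb = resize(
        np.asarray(patch, dtype=np.float64) / 255.0,
        (_MOCK_THUMB, _MOCK_THUMB, 3),
        anti_aliasing=True,
    )
    return _mock_projection(feature_dim) @ thumb.ravel()


def extract_deep_features(
    patches: Sequence[np.ndarray], cfg: DeepConfig, backend: str | None = None
) -> np.ndarray:
    """One ``cfg.feature_dim``-long embedding per RGB patch."""
    backend = backend or cfg.backend
    if backend == "mock":
        return np.vstack([_mock_embed(p, cfg.feature_dim) for p in patches])
    if backend == "pretrained":
        return _pretrained_embed(patches, cfg)
    raise ValueError(f"unknown deep backend {backend!r}; use 'mock' or 'pretrained'")


def _pretrained_embed(patches: Sequence[np.ndarray], cfg: DeepConfig) -> np.ndarray:
    try:
        import torch  # noqa: F401
        import torchvision  # noqa: F401
    except ImportError as exc:  # pragma: no cover - optional path
        raise RuntimeError(
            "the 'pretrained' backend needs torch/torchvision with downloadable "
            "Inception v3 weights; use backend='mock' for offline runs"
        ) from exc
    raise NotImplementedError(  # pragma: no cover - optional path
        "hook up torchvision.models.inception_v3 pooled activations here"
    )


@dataclass
class SoftmaxHead:
    """Trained multinomial logistic scorer over embeddings."""

    scaler: StandardScaler
    estimator: SGDClassifier

    def predict_scores(self, embeddings: np.ndarray) -> np.ndarray:
        """Simplex-valid (m, 3) score rows in (CLL, FL, MCL) order."""
        z = self.scaler.transform(np.asarray(embeddings, dtype=np.float64))
        proba = self.estimator.predict_proba(z)
        scores = np.zeros((z.shape[0], N_CLASSES))
        for j, cls in enumerate(self.estimator.classes_):
            scores[:, CLASSES.index(cls)] = proba[:, j]
        return scores


def fit_softmax_head(
    embeddings: np.ndarray,
    labels: Sequence[str],
    cfg: DeepConfig,
    seed: int = 0,
) -> SoftmaxHead:
    """Train the softmax head by seeded minibatch gradient descent.

    Runs ``cfg.iterations`` SGD steps on log-loss with constant
    learning rate ``cfg.learning_rate`` and minibatches of
    ``cfg.batch_size``, after per-dimension standardization.
    """
    X = np.asarray(embeddings, dtype=np.float64)
    y = np.asarray(labels)
    present = np.unique(y)
    if len(present) < 2:
        raise ValueError("softmax head needs at least two classes")
    scaler = StandardScaler().fit(X)
    Xz = scaler.transform(X)
    est = SGDClassifier(
        loss="log_loss",
        learning_rate="constant",
        eta0=cfg.learning_rate,
        random_state=seed,
    )
    rng = np.random.default_rng(seed)
    classes = np.asarray(sorted(present))
    batch = min(cfg.batch_size, X.shape[0])
    for _ in range(cfg.iterations):
        idx = rng.choice(X.shape[0], size=batch, replace=False)
        est.partial_fit(Xz[idx], y[idx], classes=classes)
    return SoftmaxHead(scaler=scaler, estimator=est)
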