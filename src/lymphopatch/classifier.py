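"""Patch-level random-forest classification on handcrafted feature sets.

Feature sets are named blocks assembled in a fixed order:
``F1 = {r_LBP, r_sta}`` (508 dims) and ``F2 = {r_LBP, r_sta, r_Lab}``
(1188 dims); any single block is also a valid feature set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .config import CLASSES, ClassifierConfig, N_CLASSES

#: Block composition of each named feature set, in concatenation order.
FEATURE_SETS: dict[str, tuple[str, ...]] = {
    "r_LBP": ("r_LBP",),
    "r_sta": ("r_sta",),
    "r_Lab": ("r_Lab",),
    "F1": ("r_LBP", "r_sta"),
    "F2": ("r_LBP", "r_sta", "r_Lab"),
    "deep": ("r_G",),
}


def assemble_feature_set(blocks: Mapping[str, np.ndarray], feature_set_id: str) -> np.ndarray:
    """Concatenate the named blocks of one parent patch into a flat vector."""
    if feature_set_id not in FEATURE_SETS:
        raise KeyError(f"unknown feature set {feature_set_id!r}")
    parts = []
    for name in FEATURE_SETS[feature_set_id]:
        if name not in blocks:
            raise KeyError(f"feature block {name!r} missing from the feature set")
        parts.append(np.asarray(blocks[name], dtype=np.float64).ravel())
    return np.concatenate(parts)


def assemble_matrix(
    block_rows: Sequence[Mapping[str, np.ndarray]], feature_set_id: str
) -> np.ndarray:
    """Stack assembled feature vectors of many parent patches into a matrix."""
    return np.vstack([assemble_feature_set(b, feature_set_id) for b in block_rows])


def _schema_hash(feature_set_id: str, n_features: int) -> str:
    payload = json.dumps({"feature_set": feature_set_id, "n_features": n_features})
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PatchModel:
    """A trained patch classifier plus its provenance metadata."""

    estimator: RandomForestClassifier
    feature_set_id: str
    n_trees: int
    random_seed: int
    n_features: int
    schema_hash: str


def train_patch_classifier(
    X: np.ndarray, y: Sequence[str], cfg: ClassifierConfig
) -> PatchModel:
    """Fit a seeded random forest on parent-patch feature rows.

    ``y`` holds class names; at least two classes must be present.
    Hyperparameters beyond ``n_trees`` stay at library defaults and are
    recorded in the returned metadata.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class; need at least two")
    est = RandomForestClassifier(n_estimators=cfg.n_trees, random_state=cfg.random_seed)
    est.fit(X, y)
    return PatchModel(
        estimator=est,
        feature_set_id=cfg.feature_set_id,
        n_trees=cfg.n_trees,
        random_seed=cfg.random_seed,
        n_features=X.shape[1],
        schema_hash=_schema_hash(cfg.feature_set_id, X.shape[1]),
    )


def predict_patch_scores(model: PatchModel, X: np.ndarray) -> np.ndarray:
    """Class-probability rows in the fixed (CLL, FL, MCL) order.

    Each row is a valid probability vector; rows are deterministic for
    a fixed model.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.n_features:
        raise ValueError(
            f"feature dimension {X.shape[1] if X.ndim == 2 else X.shape} does not match "
            f"the model's {model.n_features}"
        )
    proba = model.estimator.predict_proba(X)
    scores = np.zeros((X.shape[0], N_CLASSES))
    for j, cls in enumerate(model.estimator.classes_):
        scores[:, CLASSES.index(cls)] = proba[:, j]
    return scores


def split_dataset(
    image_ids: Sequence[str],
    labels: Sequence[str],
    ratio: float = 0.7,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Stratified image-level train/test split.

    All patches of an image stay on one side of the split. Per class,
    ``round(ratio * n)`` images go to training (at least one on each
    side); reproducible given ``seed``.
    """
    if not (0.0 < ratio < 1.0):
        raise ValueError(f"ratio must be in (0,1), got {ratio}")
    image_ids = list(image_ids)
    labels = list(labels)
    rng = np.random.default_rng(seed)
    train: list[str] = []
    test: list[str] = []
    for cls in sorted(set(labels)):
        members = [i for i, lab in zip(image_ids, labels) if lab == cls]
        if len(members) < 2:
            raise ValueError(f"class {cls!r} has {len(members)} image(s); need >= 2 to split")
        order = rng.permutation(len(members))
        n_train = int(round(ratio * len(members)))
        n_train = min(max(n_train, 1), len(members) - 1)
        train.extend(members[k] for k in order[:n_train])
        test.extend(members[k] for k in order[n_train:])
    return train, test


def save_model(model: PatchModel, path: str | Path) -> None:
    """Serialize a model with its embedded config and feature schema."""
    joblib.dump(model, path)


def load_model(path: str | Path) -> PatchModel:
    model = joblib.load(path)
    if not isinstance(model, PatchModel):
        raise TypeError(f"{path} does not contain a PatchModel")
    return model
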