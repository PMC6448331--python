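"""End-to-end orchestration: transform, featurize, train, aggregate.

The central objects are per-image :class:`ImageFeatures` (one block
dict per parent patch) and :func:`run_experiment`, which generates a
synthetic dataset, splits it at the image level, trains the requested
paths, and reports patch- and image-level predictions and metrics for
the chosen combination modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import synthetic
from .aggregation import PatchScores, run_combination_mode
from .classifier import (
    FEATURE_SETS,
    PatchModel,
    assemble_matrix,
    predict_patch_scores,
    split_dataset,
    train_patch_classifier,
)
from .config import (
    CLASSES,
    ClassifierConfig,
    DeepConfig,
    FusionConfig,
    LBPConfig,
    PatchConfig,
    SynthConfig,
)
from .deep_features import extract_deep_features, fit_softmax_head
from .evaluation import compute_metrics, make_prediction_table
from .features import (
    aggregate_parent,
    gray_stats,
    histogram_from_codes,
    lab_color_histogram,
    ulbp_codes,
)
from .image_spaces import quantize_blue_ratio, rgb_to_lab, to_blue_ratio
from .patching import PatchGrid, build_grid


@dataclass
class ImageFeatures:
    """Per-parent-patch feature blocks of one image."""

    image_id: str
    grid: PatchGrid
    blocks: list[dict[str, np.ndarray]] = field(default_factory=list)

    @property
    def m(self) -> int:
        return len(self.blocks)


def extract_image_features(
    rgb: np.ndarray,
    image_id: str,
    patch_cfg: PatchConfig,
    lbp_cfg: LBPConfig,
    gamma: bool = True,
) -> ImageFeatures:
    """Handcrafted feature blocks (r_LBP, r_sta, r_Lab) per parent patch.

    The blue-ratio image is min-max quantized to 8-bit once per image;
    ULBP code images are computed once per parent and sliced per
    subpatch (codes of a subpatch's interior pixels only depend on
    pixels inside the subpatch, so this is exact).
    """
    br8 = quantize_blue_ratio(to_blue_ratio(rgb))
    lab = rgb_to_lab(rgb, gamma=gamma)
    grid = build_grid(image_id, br8.shape, patch_cfg)
    s1, s2 = patch_cfg.s1, patch_cfg.s2
    out = ImageFeatures(image_id=image_id, grid=grid)
    for parent in grid.parents:
        br_parent = br8[parent.top : parent.top + s1, parent.left : parent.left + s1]
        lab_parent = lab[parent.top : parent.top + s1, parent.left : parent.left + s1]
        code_imgs = {
            r: ulbp_codes(br_parent, r, p=lbp_cfg.p, strict_gt=lbp_cfg.strict_gt)
            for r in lbp_cfg.radii
        }
        lbp_rows, sta_rows, lab_rows = [], [], []
        for top, left in grid.subpatch_offsets:
            hists = []
            for r in lbp_cfg.radii:
                # code image covers parent pixels [r, s1-r); the subpatch
                # interior [top+r, top+s2-r) maps to code rows [top, top+s2-2r)
                sub_codes = code_imgs[r][top : top + s2 - 2 * r, left : left + s2 - 2 * r]
                hists.append(histogram_from_codes(sub_codes, p=lbp_cfg.p))
            lbp_rows.append(np.concatenate(hists))
            sta_rows.append(gray_stats(br_parent[top : top + s2, left : left + s2]))
            lab_rows.append(lab_color_histogram(lab_parent[top : top + s2, left : left + s2]))
        out.blocks.append(
            {
                "r_LBP": aggregate_parent(lbp_rows),
                "r_sta": aggregate_parent(sta_rows),
                "r_Lab": aggregate_parent(lab_rows),
            }
        )
    return out


def extract_deep_path(
    rgb: np.ndarray, image_id: str, deep_cfg: DeepConfig
) -> tuple[PatchGrid, np.ndarray]:
    """Non-overlapping s3 x s3 parent patches and their embeddings."""
    s3 = deep_cfg.s3
    grid = build_grid(image_id, rgb.shape[:2], PatchConfig(s1=s3, s2=min(s3, 50)))
    patches = [
        rgb[p.top : p.top + s3, p.left : p.left + s3] for p in grid.parents
    ]
    return grid, extract_deep_features(patches, deep_cfg)


def features_to_table(feats: Sequence[ImageFeatures], labels: dict[str, str]) -> pd.DataFrame:
    """Flatten per-parent blocks into one row per parent patch."""
    rows = []
    for imf in feats:
        for parent, blocks in zip(imf.grid.parents, imf.blocks):
            row: dict[str, object] = {
                "image_id": imf.image_id,
                "parent_row": parent.row,
                "parent_col": parent.col,
                "label": labels[imf.image_id],
            }
            for name in ("r_LBP", "r_sta", "r_Lab"):
                for k, v in enumerate(blocks[name]):
                    row[f"{name}_{k:03d}"] = v
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class ExperimentResult:
    """Patch- and image-level predictions and metrics of one run."""

    patch_table: pd.DataFrame
    image_tables: dict[str, pd.DataFrame]
    patch_metrics: dict
    image_metrics: dict[str, dict]
    train_ids: list[str]
    test_ids: list[str]


def run_experiment(
    n_train_per_class: int,
    n_test_per_class: int,
    seed: int,
    synth_cfg: SynthConfig | None = None,
    patch_cfg: PatchConfig | None = None,
    lbp_cfg: LBPConfig | None = None,
    clf_cfg: ClassifierConfig | None = None,
    fusion_cfg: FusionConfig | None = None,
    deep_cfg: DeepConfig | None = None,
    modes: Sequence[str] = ("C3",),
) -> ExperimentResult:
    """Synthetic end-to-end run.

    Generates a balanced dataset, splits it stratified at the image
    level, trains F1- and F2-path random forests (and, when a mode
    requires it, the mock deep path), and evaluates the requested
    combination modes. The reported patch-level table comes from the
    fused patch scores (the C3 substrate) when both handcrafted paths
    exist.
    """
    synth_cfg = synth_cfg or SynthConfig()
    patch_cfg = patch_cfg or PatchConfig()
    lbp_cfg = lbp_cfg or LBPConfig()
    clf_cfg = clf_cfg or ClassifierConfig()
    fusion_cfg = fusion_cfg or FusionConfig()
    needs_deep = any(m in ("C4", "C5") for m in modes)
    if needs_deep:
        deep_cfg = deep_cfg or DeepConfig()

    n_total = n_train_per_class + n_test_per_class
    images, labels, manifest = synthetic.generate_dataset(n_total, synth_cfg, seed)
    image_ids = list(manifest["image_id"])
    by_id = dict(zip(image_ids, images))
    label_of = dict(zip(image_ids, labels))

    ratio = n_train_per_class / n_total
    train_ids, test_ids = split_dataset(image_ids, labels, ratio=ratio, seed=seed)
    assert not set(train_ids) & set(test_ids)

    feats = {
        iid: extract_image_features(by_id[iid], iid, patch_cfg, lbp_cfg)
        for iid in image_ids
    }

    def stack(ids: list[str], fsid: str) -> tuple[np.ndarray, np.ndarray]:
        rows, y = [], []
        for iid in ids:
            rows.extend(feats[iid].blocks)
            y.extend([label_of[iid]] * feats[iid].m)
        return assemble_matrix(rows, fsid), np.asarray(y)

    models: dict[str, PatchModel] = {}
    for fsid in ("F1", "F2"):
        X_tr, y_tr = stack(train_ids, fsid)
        cfg = ClassifierConfig(
            n_trees=clf_cfg.n_trees, random_seed=clf_cfg.random_seed, feature_set_id=fsid
        )
        models[fsid] = train_patch_classifier(X_tr, y_tr, cfg)

    deep_head = None
    if needs_deep:
        emb_tr, y_deep = [], []
        deep_data = {iid: extract_deep_path(by_id[iid], iid, deep_cfg) for iid in image_ids}
        for iid in train_ids:
            emb = deep_data[iid][1]
            emb_tr.append(emb)
            y_deep.extend([label_of[iid]] * emb.shape[0])
        deep_head = fit_softmax_head(
            np.vstack(emb_tr), y_deep, deep_cfg, seed=clf_cfg.random_seed
        )

    # --- per-test-image paths and image-level scores -------------------
    patch_rows: dict[str, list] = {"unit_id": [], "true": [], "scores": []}
    image_scores: dict[str, list[np.ndarray]] = {m: [] for m in modes}
    for iid in test_ids:
        paths: dict[str, PatchScores] = {}
        per_path_scores = {}
        for fsid in ("F1", "F2"):
            X = assemble_matrix(feats[iid].blocks, fsid)
            s = predict_patch_scores(models[fsid], X)
            per_path_scores[fsid] = s
            paths[fsid] = PatchScores(scores=s, features=X)
        if needs_deep:
            grid_d, emb = deep_data[iid]
            paths["deep"] = PatchScores(scores=deep_head.predict_scores(emb), features=emb)

        fused = (
            fusion_cfg.w_P * per_path_scores["F1"]
            + (1.0 - fusion_cfg.w_P) * per_path_scores["F2"]
        )
        for k in range(fused.shape[0]):
            patch_rows["unit_id"].append(f"{iid}:patch{k:03d}")
            patch_rows["true"].append(label_of[iid])
            patch_rows["scores"].append(fused[k])
        for mode in modes:
            image_scores[mode].append(run_combination_mode(mode, paths, fusion_cfg))

    patch_scores = np.vstack(patch_rows["scores"])
    patch_table = make_prediction_table(
        patch_rows["unit_id"],
        patch_rows["true"],
        [CLASSES[i] for i in np.argmax(patch_scores, axis=1)],
        patch_scores,
        level="patch",
    )
    image_tables = {}
    image_metrics = {}
    for mode in modes:
        s = np.vstack(image_scores[mode])
        tab = make_prediction_table(
            test_ids,
            [label_of[iid] for iid in test_ids],
            [CLASSES[i] for i in np.argmax(s, axis=1)],
            s,
            level="image",
        )
        image_tables[mode] = tab
        image_metrics[mode] = compute_metrics(tab)

    return ExperimentResult(
        patch_table=patch_table,
        image_tables=image_tables,
        patch_metrics=compute_metrics(patch_table),
        image_metrics=image_metrics,
        train_ids=train_ids,
        test_ids=test_ids,
    )
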