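"""Dataset and artifact I/O.

Reads TIFF/PNG images, scans the benchmark-style directory layout
(``<root>/<CLL|FL|MCL>/*.tif|*.png``) or a tab-separated manifest, and
writes feature tables and prediction reports as plain delimited text.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import CLASSES

IMAGE_SUFFIXES = (".tif", ".tiff", ".png")


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file as an H x W x 3 uint8 RGB array."""
    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def scan_dataset(root: str | Path) -> pd.DataFrame:
    """Build a manifest from class subdirectories or ``manifest.tsv``.

    Returns a DataFrame with columns (image_id, class, path).
    """
    root = Path(root)
    manifest_path = root / "manifest.tsv"
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path, sep="\t")
        manifest["path"] = [
            str(root / row["class"] / f"{row['image_id']}.png")
            for _, row in manifest.iterrows()
        ]
        return manifest[["image_id", "class", "path"]]
    rows = []
    for cls in CLASSES:
        cls_dir = root / cls
        if not cls_dir.is_dir():
            continue
        for p in sorted(cls_dir.iterdir()):
            if p.suffix.lower() in IMAGE_SUFFIXES:
                rows.append({"image_id": p.stem, "class": cls, "path": str(p)})
    if not rows:
        raise FileNotFoundError(f"no class subdirectories with images under {root}")
    return pd.DataFrame(rows)


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-parent-patch feature table as tab-separated text."""
    table.to_csv(path, sep="\t", index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_prediction_report(table: pd.DataFrame, path: str | Path, mode: str) -> None:
    """Per-unit prediction report: id, true label, mode, prediction, scores."""
    out = table.copy()
    out.insert(2, "mode", mode)
    out.to_csv(path, sep="\t", index=False)
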