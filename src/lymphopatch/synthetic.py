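"""Seeded generator of 3-class H&E-like RGB images.

Each image is an eosin-pink background with Gaussian pixel noise on
which dark blue-purple elliptical "nuclei" are placed by a Poisson
process. The three classes differ along the axes the real subtypes
differ on at low magnification: nuclear blob density and size (texture,
picked up by the LBP and gray-statistics blocks) and nucleus hue
(color, picked up by the Lab histograms). FL-style images additionally
cluster nuclei into follicle-like disks. Everything is deterministic
given (class_id, config, seed); no global random state is touched.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import ellipse

from .config import CLASS_TO_INDEX, CLASSES, SynthConfig


def generate_image(class_id: str, cfg: SynthConfig, seed: int) -> np.ndarray:
    """One H x W x 3 uint8 image of the requested class."""
    if class_id not in CLASSES:
        raise ValueError(f"unknown class {class_id!r}; expected one of {CLASSES}")
    params = cfg.class_params[class_id]
    h, w = cfg.image_size
    rng = np.random.default_rng([seed, CLASS_TO_INDEX[class_id]])

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(cfg.background_color, dtype=np.float64)
    img += rng.normal(0.0, cfg.noise_sd, size=img.shape)

    n_blobs = rng.poisson(params.density * h * w / 1e4)
    if params.follicle and n_blobs > 0:
        n_follicles = max(1, int(round(h * w / 1e5)))
        fol_centers = rng.uniform(0, [h, w], size=(n_follicles, 2))
    for _ in range(n_blobs):
        if params.follicle and rng.random() < cfg.follicle_fraction:
            fc = fol_centers[rng.integers(len(fol_centers))]
            cy, cx = fc + rng.normal(0.0, cfg.follicle_radius / 2.0, size=2)
        else:
            cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        r_major = rng.uniform(*params.radius_range)
        r_minor = r_major * rng.uniform(0.6, 1.0)
        rot = rng.uniform(0, np.pi)
        rr, cc = ellipse(cy, cx, r_major, r_minor, shape=(h, w), rotation=rot)
        if rr.size == 0:
            continue
        color = np.asarray(params.nucleus_color, dtype=np.float64) + rng.normal(0, 6, size=3)
        img[rr, cc] = 0.85 * color + 0.15 * img[rr, cc]

    return np.clip(img, 0, 255).astype(np.uint8)


def generate_dataset(
    n_per_class: int,
    cfg: SynthConfig,
    seed: int,
    out_dir: str | Path | None = None,
) -> tuple[list[np.ndarray], list[str], pd.DataFrame]:
    """Balanced labeled image set plus its manifest.

    Image ``i`` of each class is generated with per-image seed
    ``seed + i``, so disjoint seed ranges give disjoint image sets. If
    ``out_dir`` is given, images are written as PNGs in one
    subdirectory per class (the benchmark directory layout) with a
    tab-separated ``manifest.tsv``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    images: list[np.ndarray] = []
    labels: list[str] = []
    rows = []
    for cls in CLASSES:
        for i in range(n_per_class):
            img_seed = seed + i
            img = generate_image(cls, cfg, img_seed)
            image_id = f"{cls}_{i:03d}"
            images.append(img)
            labels.append(cls)
            rows.append({"image_id": image_id, "class": cls, "seed": img_seed})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        for img, (_, row) in zip(images, manifest.iterrows()):
            cls_dir = out_dir / row["class"]
            cls_dir.mkdir(parents=True, exist_ok=True)
            iio.imwrite(cls_dir / f"{row['image_id']}.png", img)
        manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return images, labels, manifest
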