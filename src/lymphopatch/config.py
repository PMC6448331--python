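"""Configuration dataclasses for every pipeline stage.

All defaults reproduce the reference experimental setup: parent patch
size ``s1=200``, subpatch size ``s2=50`` with overlap ratio ``r_o=0.5``,
deep-path patch size ``s3=300``, 200 random-forest trees, fusion weights
``w_P=0.7`` and ``w_I=0.5``, and a 7:3 image-level train/test split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

#: Fixed class order used everywhere (alphabetical).
CLASSES: tuple[str, ...] = ("CLL", "FL", "MCL")
CLASS_TO_INDEX: dict[str, int] = {c: i for i, c in enumerate(CLASSES)}
N_CLASSES = len(CLASSES)


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class PatchConfig:
    """Two-level crop geometry.

    Parameters
    ----------
    s1 : parent patch window size in pixels (non-overlapping tiling).
    s2 : subpatch window size in pixels (overlapping sliding window).
    r_o : subpatch overlap ratio in ``[0, 1)``.
    s3 : deep-path patch size in pixels.
    """

    s1: int = 200
    s2: int = 50
    r_o: float = 0.5
    s3: int = 300

    def __post_init__(self) -> None:
        if not (0 < self.s2 <= self.s1):
            raise ConfigurationError(f"need 0 < s2 <= s1, got s2={self.s2}, s1={self.s1}")
        if not (0.0 <= self.r_o < 1.0):
            raise ConfigurationError(f"overlap ratio must be in [0, 1), got {self.r_o}")
        if self.s3 < 1:
            raise ConfigurationError(f"s3 must be >= 1, got {self.s3}")

    @property
    def stride(self) -> int:
        """Subpatch sliding-window stride, ``round(s2 * (1 - r_o))``."""
        stride = int(round(self.s2 * (1.0 - self.r_o)))
        if stride < 1:
            raise ConfigurationError(
                f"stride round(s2*(1-r_o)) = {stride} < 1 for s2={self.s2}, r_o={self.r_o}"
            )
        return stride


@dataclass
class LBPConfig:
    """Uniform-LBP settings: ``p`` circular samples at each radius.

    ``strict_gt=False`` marks a neighbor as 1 when it is >= the center
    (the dominant convention); ``strict_gt=True`` uses a strict >.
    """

    p: int = 8
    radii: tuple[int, ...] = (1, 2)
    strict_gt: bool = False

    def __post_init__(self) -> None:
        if self.p < 4:
            raise ConfigurationError(f"p must be >= 4, got {self.p}")
        if not self.radii or any(r < 1 for r in self.radii):
            raise ConfigurationError(f"radii must all be >= 1, got {self.radii}")
        self.radii = tuple(self.radii)

    @property
    def bins_per_radius(self) -> int:
        return self.p * (self.p - 1) + 3

    @property
    def dim_per_subpatch(self) -> int:
        return self.bins_per_radius * len(self.radii)


@dataclass
class ClassifierConfig:
    """Random-forest patch classifier settings."""

    n_trees: int = 200
    random_seed: int = 0
    feature_set_id: str = "F2"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ConfigurationError(f"n_trees must be >= 1, got {self.n_trees}")


@dataclass
class FusionConfig:
    """Patch/image-level fusion weights and combination mode.

    ``w_P`` mixes the F1- and F2-path patch scores (mode C3);
    ``w_I`` mixes the C3 and C4 image scores (mode C5).
    """

    w_P: float = 0.7
    w_I: float = 0.5
    mode: str = "C3"
    dmw_standardize: bool = True

    def __post_init__(self) -> None:
        for name in ("w_P", "w_I"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.mode not in ("C1", "C2", "C3", "C4", "C5"):
            raise ConfigurationError(f"unknown combination mode {self.mode!r}")


@dataclass
class DeepConfig:
    """Deep-path settings: patch size, embedding width, head training."""

    s3: int = 300
    feature_dim: int = 2048
    iterations: int = 500
    learning_rate: float = 0.001
    batch_size: int = 100
    backend: str = "mock"

    def __post_init__(self) -> None:
        if self.s3 < 1:
            raise ConfigurationError(f"s3 must be >= 1, got {self.s3}")
        if self.feature_dim < 1:
            raise ConfigurationError(f"feature_dim must be >= 1, got {self.feature_dim}")


@dataclass
class SynthClassParams:
    """Per-class generator parameters.

    density is in nuclear blobs per 10^4 pixels; radius_range is the
    uniform range of blob semi-major axes in pixels; nucleus_color is
    the mean RGB of the hematoxylin-stained blobs. ``follicle=True``
    clusters most blobs into follicle-like disks.
    """

    density: float
    radius_range: tuple[float, float]
    nucleus_color: tuple[int, int, int]
    follicle: bool = False

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ConfigurationError("density must be >= 0")
        lo, hi = self.radius_range
        if not (0 < lo <= hi):
            raise ConfigurationError(f"bad radius_range {self.radius_range}")


def _default_class_params() -> dict[str, SynthClassParams]:
    # Chosen so nuclear coverage x nuclear blue-ratio strictly follows
    # the density ordering CLL > FL > MCL, and the nucleus hue carries
    # class information into the Lab color blocks.
    return {
        "CLL": SynthClassParams(16.0, (3.0, 4.0), (60, 40, 150)),
        "FL": SynthClassParams(6.0, (4.0, 6.0), (90, 50, 140), follicle=True),
        "MCL": SynthClassParams(1.5, (6.0, 9.0), (110, 60, 120)),
    }


@dataclass
class SynthConfig:
    """3-class H&E-like image generator settings."""

    image_size: tuple[int, int] = (600, 600)
    background_color: tuple[int, int, int] = (240, 185, 205)
    noise_sd: float = 8.0
    follicle_radius: float = 70.0
    follicle_fraction: float = 0.8
    class_params: dict[str, SynthClassParams] = field(default_factory=_default_class_params)

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 1 or w < 1:
            raise ConfigurationError(f"bad image_size {self.image_size}")
        triples = [
            (p.density, tuple(p.radius_range), tuple(p.nucleus_color))
            for p in self.class_params.values()
        ]
        if len(set(triples)) != len(triples):
            raise ConfigurationError("class parameter triples must be pairwise distinct")


@dataclass
class RunConfig:
    """Aggregate configuration for a full pipeline run."""

    patch: PatchConfig = field(default_factory=PatchConfig)
    lbp: LBPConfig = field(default_factory=LBPConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    deep: DeepConfig = field(default_factory=DeepConfig)
    synth: SynthConfig = field(default_factory=SynthConfig)
    split_ratio: float = 0.7
    seed: int = 0
    gamma: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.split_ratio < 1.0):
            raise ConfigurationError(f"split_ratio must be in (0,1), got {self.split_ratio}")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        synth = d.get("synth")
        if synth is not None:
            synth = dict(synth)
            cp = synth.get("class_params")
            if cp is not None:
                synth["class_params"] = {
                    k: SynthClassParams(**_tupled(v)) for k, v in cp.items()
                }
            for key in ("image_size", "background_color"):
                if key in synth and synth[key] is not None:
                    synth[key] = tuple(synth[key])
            d["synth"] = SynthConfig(**synth)
        for key, klass in (
            ("patch", PatchConfig),
            ("lbp", LBPConfig),
            ("classifier", ClassifierConfig),
            ("fusion", FusionConfig),
            ("deep", DeepConfig),
        ):
            if key in d and isinstance(d[key], dict):
                sub = dict(d[key])
                if key == "lbp" and "radii" in sub:
                    sub["radii"] = tuple(sub["radii"])
                d[key] = klass(**sub)
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _tupled(d: dict[str, Any]) -> dict[str, Any]:
    d = dict(d)
    for key in ("radius_range", "nucleus_color"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    return d
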