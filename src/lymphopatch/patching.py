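"""Two-level patch geometry.

Parent patches tile the image without overlap (incomplete border
windows are discarded so every patch has the same size); subpatches
slide inside each parent with a configurable overlap ratio. All
coordinates are 0-based with half-open windows ``[top, top + s)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import ConfigurationError, PatchConfig


@dataclass(frozen=True)
class ParentPatch:
    """One parent window: grid indices plus pixel coordinates."""

    row: int
    col: int
    top: int
    left: int


@dataclass
class PatchGrid:
    """All parent windows of one image plus the shared subwindow offsets."""

    image_id: str
    s1: int
    n_rows: int
    n_cols: int
    parents: list[ParentPatch] = field(default_factory=list)
    subpatch_offsets: list[tuple[int, int]] = field(default_factory=list)

    @property
    def m(self) -> int:
        """Number of parent patches."""
        return len(self.parents)


def crop_parent_patches(img_shape: tuple[int, int], s1: int) -> list[ParentPatch]:
    """Row-major non-overlapping ``s1 x s1`` tiling of an ``(H, W)`` image.

    Yields ``floor(H/s1) * floor(W/s1)`` windows; right/bottom
    remainders are discarded.
    """
    h, w = img_shape
    if s1 < 1 or s1 > min(h, w):
        raise ConfigurationError(f"parent size s1={s1} does not fit image shape {img_shape}")
    n_rows, n_cols = h // s1, w // s1
    return [
        ParentPatch(row=i, col=j, top=i * s1, left=j * s1)
        for i in range(n_rows)
        for j in range(n_cols)
    ]


def crop_subpatches(s1: int, s2: int, r_o: float) -> list[tuple[int, int]]:
    """Sliding ``s2 x s2`` subwindow offsets inside an ``s1 x s1`` parent.

    Offsets run 0, stride, 2*stride, ... with
    ``stride = round(s2 * (1 - r_o))``, keeping only windows fully
    inside the parent; the same offsets apply on both axes, row-major.
    """
    if not (0 < s2 <= s1):
        raise ConfigurationError(f"need 0 < s2 <= s1, got s2={s2}, s1={s1}")
    stride = int(round(s2 * (1.0 - r_o)))
    if stride < 1:
        raise ConfigurationError(f"stride round(s2*(1-r_o)) = {stride} < 1")
    positions = list(range(0, s1 - s2 + 1, stride))
    return [(top, left) for top in positions for left in positions]


def build_grid(image_id: str, img_shape: tuple[int, int], cfg: PatchConfig) -> PatchGrid:
    """Assemble the full two-level grid for one image."""
    parents = crop_parent_patches(img_shape, cfg.s1)
    offsets = crop_subpatches(cfg.s1, cfg.s2, cfg.r_o)
    h, w = img_shape
    return PatchGrid(
        image_id=image_id,
        s1=cfg.s1,
        n_rows=h // cfg.s1,
        n_cols=w // cfg.s1,
        parents=parents,
        subpatch_offsets=offsets,
    )
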