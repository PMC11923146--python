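"""Square tiling of rectangular sign annotations, plus training augmentations.

OSSN-related signs are annotated as axis-aligned rectangles. Because the
distinguishing texture of a sign survives in sub-regions, each rectangle of
size ``w x h`` is cut into ``ceil(max(w, h) / min(w, h))`` square tiles whose
side equals the shorter rectangle side. Tiles advance along the long axis with
a stride of one side length; the final tile is anchored flush with the far
edge and may therefore overlap its predecessor. All tiles inherit a shared
``group_id`` so that downstream splitting can keep tiles born from one
annotation on one side of a train/validation boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import transform as sktransform

OSSN_SIGN_CLASSES = ("starry_sky", "hyperkeratosis", "mitosis", "irregular_cells")

__all__ = [
    "OSSN_SIGN_CLASSES",
    "RectAnnotation",
    "SquareTile",
    "AugmentConfig",
    "tile_count",
    "split_rectangle",
    "augment",
]


@dataclass(frozen=True)
class RectAnnotation:
    """An axis-aligned sign rectangle on one image.

    Coordinates are 0-based with origin at the top-left; the rectangle covers
    the half-open pixel range ``[x, x + w) x [y, y + h)``.
    """

    annotation_id: str
    image_id: str
    sign_class: str
    x: int
    y: int
    w: int
    h: int

    def __post_init__(self) -> None:
        if self.w < 1 or self.h < 1:
            raise ValueError(
                f"annotation {self.annotation_id!r}: sides must be >= 1, got "
                f"w={self.w}, h={self.h}"
            )
        if self.x < 0 or self.y < 0:
            raise ValueError(f"annotation {self.annotation_id!r}: negative origin")


@dataclass(frozen=True)
class SquareTile:
    """One square sub-image cut from a parent annotation."""

    tile_id: str
    parent_annotation_id: str
    image_id: str
    sign_class: str
    x: int
    y: int
    side: int
    group_id: str = field(default="")

    def __post_init__(self) -> None:
        if not self.group_id:
            object.__setattr__(self, "group_id", self.parent_annotation_id)


def tile_count(w: int, h: int) -> int:
    """Number of square tiles a ``w x h`` rectangle is divided into.

    Equals ``ceil(max(w, h) / min(w, h))``: 1 for a square, at least 2 for any
    non-square rectangle. Symmetric in its arguments.
    """
    if w < 1 or h < 1:
        raise ValueError(f"rectangle sides must be >= 1, got ({w}, {h})")
    return math.ceil(max(w, h) / min(w, h))


def split_rectangle(rect: RectAnnotation) -> list[SquareTile]:
    """Cut ``rect`` into square tiles of side ``min(w, h)`` along its long axis.

    Tiles are placed at stride ``side`` starting from the near edge; the last
    tile is anchored flush with the far edge, so for fractional aspect ratios
    it overlaps the previous one. The union of tiles always covers the whole
    rectangle, and every tile lies inside it.
    """
    side = min(rect.w, rect.h)
    long_len = max(rect.w, rect.h)
    n = tile_count(rect.w, rect.h)
    offsets = [i * side for i in range(n - 1)]
    offsets.append(long_len - side)  # flush with the far edge
    along_x = rect.w >= rect.h
    tiles = []
    for i, off in enumerate(offsets):
        tx = rect.x + off if along_x else rect.x
        ty = rect.y if along_x else rect.y + off
        tiles.append(
            SquareTile(
                tile_id=f"{rect.annotation_id}:{i}",
                parent_annotation_id=rect.annotation_id,
                image_id=rect.image_id,
                sign_class=rect.sign_class,
                x=tx,
                y=ty,
                side=side,
            )
        )
    return tiles


def extract_tile_pixels(pixels: np.ndarray, tile: SquareTile) -> np.ndarray:
    """Slice a tile's pixel block out of its parent content-area image."""
    return pixels[tile.y : tile.y + tile.side, tile.x : tile.x + tile.side]


@dataclass(frozen=True)
class AugmentConfig:
    """Stochastic training augmentation settings.

    ``rotation_deg`` bounds a rotation drawn uniformly from
    ``[-rotation_deg, +rotation_deg]``; ``scale_prob`` / ``flip_prob`` are the
    probabilities of applying a scale jitter (uniform in ``1 +- scale_range``)
    and a horizontal flip. Defaults follow the training recipe: 10-degree
    rotation, scaling and flipping each with probability 0.5.
    """

    rotation_deg: float = 10.0
    scale_prob: float = 0.5
    scale_range: float = 0.10
    flip_prob: float = 0.5
    enabled: bool = True


def _scale_jitter(img: np.ndarray, factor: float) -> np.ndarray:
    """Zoom by ``factor`` about the center, returning the original shape."""
    side = img.shape[0]
    new_side = max(1, int(round(side * factor)))
    scaled = sktransform.resize(
        img, (new_side, new_side), order=1, mode="reflect", anti_aliasing=False
    )
    if new_side == side:
        return scaled
    if new_side > side:  # zoom in: center crop
        off = (new_side - side) // 2
        return scaled[off : off + side, off : off + side]
    # zoom out: reflect-pad back to size
    pad = side - new_side
    before = pad // 2
    return np.pad(scaled, ((before, pad - before), (before, pad - before)), mode="reflect")


def augment(
    tile_pixels: np.ndarray, rng: np.random.Generator, config: AugmentConfig | None = None
) -> np.ndarray:
    """Apply rotation, then optional scale jitter, then optional horizontal flip.

    The input must be square. Rotation uses reflection padding so no empty
    corners are introduced. The output has the same shape and dtype float;
    identical ``rng`` states yield identical outputs.
    """
    if config is None:
        config = AugmentConfig()
    if tile_pixels.ndim != 2 or tile_pixels.shape[0] != tile_pixels.shape[1]:
        raise ValueError(f"augment expects a square 2-D tile, got shape {tile_pixels.shape}")
    out = np.asarray(tile_pixels, dtype=float)
    if not config.enabled:
        return out.copy()
    angle = rng.uniform(-config.rotation_deg, config.rotation_deg)
    if angle != 0.0:
        out = sktransform.rotate(out, angle, mode="reflect", preserve_range=True)
    if rng.random() < config.scale_prob:
        factor = 1.0 + rng.uniform(-config.scale_range, config.scale_range)
        out = _scale_jitter(out, factor)
    if rng.random() < config.flip_prob:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)
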