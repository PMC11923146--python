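"""Watershed cell segmentation over the content-area mosaic.

Confocal epithelial mosaics show bright cell borders around dark interiors,
so cells are recovered classically: smooth, threshold the dark interiors,
split touching regions by a distance-transform watershed, and filter by
area. The segmenter sits behind a registry so a different callable (e.g. a
learned instance segmenter) can be swapped in by name without touching the
callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
from scipy import ndimage
from skimage import feature, filters, segmentation

from .preprocess import IvcmImage

__all__ = [
    "CellInstance",
    "SegmenterParams",
    "segment_cells",
    "match_labels",
    "register_segmenter",
    "get_segmenter",
]


@dataclass(frozen=True)
class SegmenterParams:
    """Classical segmenter knobs: smoothing, area gates, watershed splitting."""

    smooth_sigma: float = 1.4
    min_area: int = 30
    max_area: int = 5000
    min_peak_distance: int = 8


@dataclass
class CellInstance:
    """One segmented cell: mask, box, area and (optionally) its binary label."""

    cell_id: str
    image_id: str
    mask: np.ndarray  # bool, content-area shape
    bbox: tuple[int, int, int, int]  # x, y, w, h
    area: int
    label: bool | None = None  # True = OSSN-related
    matched: bool = True

    @property
    def centroid(self) -> tuple[float, float]:
        ys, xs = np.nonzero(self.mask)
        return float(xs.mean()), float(ys.mean())


def _watershed_segment(pixels: np.ndarray, params: SegmenterParams) -> np.ndarray:
    """Return an integer label map (0 = background/borders).

    Bright borders disconnect cell interiors, so connected components of the
    sub-Otsu (dark) region recover most cells directly; components larger
    than ``max_area`` — fused interiors whose shared border ridge is broken —
    are split by a distance-transform watershed.
    """
    img = ndimage.gaussian_filter(np.asarray(pixels, dtype=float), params.smooth_sigma)
    if img.max() - img.min() < 1e-9:  # blank frame: nothing to segment
        return np.zeros(pixels.shape, dtype=int)
    interior = img < filters.threshold_otsu(img)
    interior = ndimage.binary_opening(interior, iterations=1)
    if not interior.any():
        return np.zeros(pixels.shape, dtype=int)
    label_map, n = ndimage.label(interior)
    out = np.zeros(pixels.shape, dtype=int)
    next_id = 1
    for k, sl in enumerate(ndimage.find_objects(label_map), start=1):
        comp = label_map[sl] == k
        area = int(comp.sum())
        if area <= params.max_area:
            out[sl][comp] = next_id
            next_id += 1
            continue
        dist = ndimage.distance_transform_edt(comp)
        peaks = feature.peak_local_max(
            dist, min_distance=params.min_peak_distance, labels=comp
        )
        if len(peaks) < 2:
            out[sl][comp] = next_id
            next_id += 1
            continue
        markers = np.zeros(comp.shape, dtype=int)
        for i, (py, px) in enumerate(peaks, start=1):
            markers[py, px] = i
        pieces = segmentation.watershed(-dist, markers, mask=comp)
        for piece_id in range(1, pieces.max() + 1):
            piece = pieces == piece_id
            if piece.any():
                out[sl][piece] = next_id
                next_id += 1
    return out


def segment_cells(
    image: IvcmImage, params: SegmenterParams | None = None
) -> list[CellInstance]:
    """Segment individual cells from a footer-free content image.

    Deterministic for fixed parameters; returns instances whose masks are
    pairwise disjoint and whose areas lie in ``[min_area, max_area]``. An
    empty list (e.g. for a blank image) is a valid result.
    """
    if not image.footer_removed:
        raise ValueError("segment_cells expects the footer to be removed first")
    if params is None:
        params = SegmenterParams()
    label_map = _watershed_segment(image.pixels, params)
    instances: list[CellInstance] = []
    for k, sl in enumerate(ndimage.find_objects(label_map), start=1):
        if sl is None:
            continue
        mask = np.zeros(label_map.shape, dtype=bool)
        region = label_map[sl] == k
        area = int(region.sum())
        if not params.min_area <= area <= params.max_area:
            continue
        mask[sl] = region
        y0, y1 = sl[0].start, sl[0].stop
        x0, x1 = sl[1].start, sl[1].stop
        instances.append(
            CellInstance(
                cell_id=f"{image.image_id}_S{len(instances):04d}",
                image_id=image.image_id,
                mask=mask,
                bbox=(x0, y0, x1 - x0, y1 - y0),
                area=area,
            )
        )
    return instances


def match_labels(
    instances: list[CellInstance],
    truth_label_map: np.ndarray,
    truth_labels: Mapping[int, bool],
) -> list[CellInstance]:
    """Assign each instance the majority ground-truth label under its mask.

    ``truth_label_map`` is the generator's integer cell map (0 = background);
    ``truth_labels`` maps truth cell ids to their binary OSSN flag. An
    instance whose mask covers only background is flagged unmatched for
    expert review rather than being given a label.
    """
    for inst in instances:
        overlap = truth_label_map[inst.mask]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            inst.label = None
            inst.matched = False
            continue
        ids, counts = np.unique(overlap, return_counts=True)
        winner = int(ids[np.argmax(counts)])
        inst.label = bool(truth_labels[winner])
        inst.matched = True
    return instances


# ---------------------------------------------------------------------------
# pluggable segmenter registry
# ---------------------------------------------------------------------------

SegmenterFn = Callable[[IvcmImage, SegmenterParams | None], list[CellInstance]]
_REGISTRY: dict[str, SegmenterFn] = {"watershed": segment_cells}


def register_segmenter(name: str, fn: SegmenterFn) -> None:
    """Register a segmentation callable under ``name``."""
    _REGISTRY[name] = fn


def get_segmenter(name: str) -> SegmenterFn:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"no segmenter {name!r}; registered: {sorted(_REGISTRY)}"
        ) from None
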