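"""Image ingestion, footer removal, quality screening and CVAT annotation I/O.

HRT-II confocal snapshots are 384 x 484 grayscale frames whose bottom 100
rows hold a meta-information footer (device settings, depth, patient text).
The footer is cropped away before any analysis so classifiers can only see
the cellular content; images failing quality screening (blur, poor contrast)
are excluded. Sign rectangles are exchanged in CVAT-for-images 1.1 XML.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

from .tiling import OSSN_SIGN_CLASSES, RectAnnotation

RAW_WIDTH = 384
RAW_HEIGHT = 484
CONTENT_SIDE = 384
FOOTER_HEIGHT = RAW_HEIGHT - CONTENT_SIDE

IMAGE_CLASSES = ("OSSN", "normal", "melanoma", "pterygium", "keratitis")

#: sign classes accepted in CVAT files: the four OSSN signs plus the
#: non-OSSN distractor tag used for control rectangles.
KNOWN_SIGN_CLASSES = OSSN_SIGN_CLASSES + ("non_ossn",)


class DimensionError(ValueError):
    """Raised when an image does not have the geometry an operation requires."""


@dataclass
class IvcmImage:
    """One grayscale IVCM snapshot with its identity and label metadata."""

    image_id: str
    pixels: np.ndarray  # uint8, (H, W)
    patient_id: str
    class_label: str = "unknown"
    footer_removed: bool = False

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class QualityReport:
    """Outcome of quality screening; ``passed`` iff ``reasons`` is empty."""

    passed: bool
    blur_score: float
    contrast_score: float
    reasons: tuple[str, ...] = field(default_factory=tuple)


def crop_footer(image: IvcmImage) -> IvcmImage:
    """Return the 384 x 384 content region, dropping the meta-information footer.

    The crop is a pure slice: pixels in the content region are bit-identical
    to the source. Refuses (rather than silently re-crops) images that are
    already cropped or have unexpected geometry.
    """
    if image.footer_removed:
        raise DimensionError(f"image {image.image_id!r} already has its footer removed")
    if image.height != RAW_HEIGHT or image.width != RAW_WIDTH:
        raise DimensionError(
            f"image {image.image_id!r}: expected {RAW_WIDTH} x {RAW_HEIGHT}, "
            f"got {image.width} x {image.height}"
        )
    return replace(
        image, pixels=image.pixels[:CONTENT_SIDE, :].copy(), footer_removed=True
    )


def blur_score(pixels: np.ndarray) -> float:
    """Sharpness proxy: variance of the discrete Laplacian response."""
    lap = ndimage.laplace(np.asarray(pixels, dtype=float))
    return float(lap.var())


def contrast_score(pixels: np.ndarray) -> float:
    """Robust dynamic range: the p99 - p1 intensity spread."""
    p1, p99 = np.percentile(np.asarray(pixels, dtype=float), [1, 99])
    return float(p99 - p1)


def quality_screen(
    image: IvcmImage,
    blur_threshold: float = 20.0,
    contrast_threshold: float = 40.0,
) -> QualityReport:
    """Screen a cropped image against blur and contrast thresholds.

    An image fails with reason ``"blur"`` when the Laplacian-variance score
    falls below ``blur_threshold`` and with ``"low_contrast"`` when the robust
    intensity range falls below ``contrast_threshold``. The default thresholds
    were calibrated once on the synthetic cohort; they are configuration, not
    clinical claims.
    """
    if not image.footer_removed:
        raise DimensionError("quality_screen expects the footer to be removed first")
    b = blur_score(image.pixels)
    c = contrast_score(image.pixels)
    reasons: list[str] = []
    if b < blur_threshold:
        reasons.append("blur")
    if c < contrast_threshold:
        reasons.append("low_contrast")
    return QualityReport(
        passed=not reasons, blur_score=b, contrast_score=c, reasons=tuple(reasons)
    )


def load_image(path: str | Path, patient_id: str = "", class_label: str = "unknown") -> IvcmImage:
    """Read a PNG/JPEG snapshot as an 8-bit grayscale :class:`IvcmImage`."""
    path = Path(path)
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.uint8)
    return IvcmImage(
        image_id=path.stem,
        pixels=arr,
        patient_id=patient_id,
        class_label=class_label,
        footer_removed=arr.shape[0] != RAW_HEIGHT,
    )


def save_image(image: IvcmImage, path: str | Path) -> None:
    """Write an image losslessly as PNG (or JPEG if the suffix asks for it)."""
    Image.fromarray(image.pixels, mode="L").save(Path(path))


# ---------------------------------------------------------------------------
# CVAT-for-images 1.1 XML
# ---------------------------------------------------------------------------


class CvatParseError(ValueError):
    """Raised for malformed CVAT XML or unknown sign classes."""


def read_cvat(path: str | Path) -> list[RectAnnotation]:
    """Parse a CVAT-for-images 1.1 file into rectangle annotations.

    Only ``<box>`` elements are consumed; boxes carry ``xtl/ytl/xbr/ybr``
    corner coordinates which are converted to the package's ``(x, y, w, h)``
    convention. Unknown sign labels raise a parse error naming the element.
    """
    try:
        tree = ET.parse(str(path))
    except ET.ParseError as exc:
        raise CvatParseError(f"malformed CVAT XML in {path}: {exc}") from exc
    root = tree.getroot()
    annotations: list[RectAnnotation] = []
    for image_el in root.iter("image"):
        image_id = image_el.get("name") or image_el.get("id") or ""
        for k, box in enumerate(image_el.iter("box")):
            label = box.get("label")
            if label not in KNOWN_SIGN_CLASSES:
                raise CvatParseError(
                    f"unknown sign class {label!r} on box {k} of image {image_id!r}"
                )
            try:
                xtl = float(box.get("xtl"))
                ytl = float(box.get("ytl"))
                xbr = float(box.get("xbr"))
                ybr = float(box.get("ybr"))
            except (TypeError, ValueError) as exc:
                raise CvatParseError(
                    f"box {k} of image {image_id!r} has malformed coordinates"
                ) from exc
            annotations.append(
                RectAnnotation(
                    annotation_id=f"{image_id}:{k}",
                    image_id=image_id,
                    sign_class=label,
                    x=int(round(xtl)),
                    y=int(round(ytl)),
                    w=int(round(xbr - xtl)),
                    h=int(round(ybr - ytl)),
                )
            )
    return annotations


def write_cvat(
    annotations: list[RectAnnotation],
    path: str | Path,
    image_size: tuple[int, int] = (CONTENT_SIDE, CONTENT_SIDE),
) -> None:
    """Write annotations as CVAT-for-images 1.1 XML.

    ``write_cvat`` then :func:`read_cvat` is the identity on
    (image id, sign class, x, y, w, h).
    """
    root = ET.Element("annotations")
    ET.SubElement(root, "version").text = "1.1"
    by_image: dict[str, list[RectAnnotation]] = {}
    for ann in annotations:
        by_image.setdefault(ann.image_id, []).append(ann)
    for idx, (image_id, anns) in enumerate(by_image.items()):
        image_el = ET.SubElement(
            root,
            "image",
            id=str(idx),
            name=image_id,
            width=str(image_size[0]),
            height=str(image_size[1]),
        )
        for ann in anns:
            ET.SubElement(
                image_el,
                "box",
                label=ann.sign_class,
                occluded="0",
                xtl=f"{ann.x:.2f}",
                ytl=f"{ann.y:.2f}",
                xbr=f"{ann.x + ann.w:.2f}",
                ybr=f"{ann.y + ann.h:.2f}",
            )
    ET.indent(root)
    ET.ElementTree(root).write(str(path), encoding="unicode", xml_declaration=True)
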