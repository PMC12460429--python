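"""Read/write YOLO-style polygon segmentation labels and rasterize them.

The label dialect is one instance per line::

    <class_id> x1 y1 x2 y2 ... xn yn

with coordinates normalized to [0, 1] relative to image width/height and the
polygon implicitly closed.  Class 0 is the citrus fruit, class 1 the stem.

Pixel convention: 0-based, x rightward, y downward, pixel centers at integer
coordinates.  Normalized x is scaled by the image width, y by the height.
Rasterization uses the even-odd rule sampled at pixel centers so that the
behaviour is bit-stable across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image

FRUIT_CLASS = 0
STEM_CLASS = 1
_VALID_CLASSES = frozenset({FRUIT_CLASS, STEM_CLASS})


class LabelFormatError(ValueError):
    """Raised for malformed label-file content; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


@dataclass(frozen=True)
class PolygonAnnotation:
    """One labelled instance: a class id and a normalized closed polygon."""

    class_id: int
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if self.class_id not in _VALID_CLASSES:
            raise ValueError(f"unknown class id {self.class_id}")
        if len(self.vertices) < 3:
            raise ValueError("polygon needs at least 3 vertices")
        for x, y in self.vertices:
            if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
                raise ValueError(f"vertex ({x}, {y}) outside [0,1]")

    def pixel_vertices(self, image_width: int, image_height: int) -> np.ndarray:
        """Vertices in pixel coordinates, shape (n, 2) as (x, y) floats."""
        v = np.asarray(self.vertices, dtype=float)
        return v * np.array([image_width, image_height], dtype=float)


@dataclass
class InstanceMask:
    """A rasterized binary instance mask with class/instance ids and confidence."""

    raster: np.ndarray  # bool, (height, width)
    class_id: int
    instance_id: int
    confidence: float = 1.0
    empty: bool = field(default=False)

    def __post_init__(self):
        self.raster = np.asarray(self.raster, dtype=bool)
        if self.raster.ndim != 2:
            raise ValueError("raster must be 2-D")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError("confidence must be in [0,1]")
        if not self.empty and not self.raster.any():
            raise ValueError("mask has no foreground; pass empty=True to allow")

    @property
    def area(self) -> int:
        return int(self.raster.sum())


def parse_labels(text: str, image_width: int, image_height: int) -> list[PolygonAnnotation]:
    """Parse label-file content into annotations, preserving line order.

    Raises :class:`LabelFormatError` naming the offending 1-based line for odd
    coordinate counts, unparseable or out-of-range values, and unknown class
    ids.  Image dimensions are accepted for interface symmetry with
    :func:`rasterize` (normalized labels do not depend on them).
    """
    del image_width, image_height  # labels are normalized; kept for symmetry
    annotations: list[PolygonAnnotation] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        tokens = raw.split()
        if not tokens:
            continue
        try:
            class_id = int(tokens[0])
        except ValueError:
            raise LabelFormatError(lineno, f"class id {tokens[0]!r} is not an integer") from None
        if class_id not in _VALID_CLASSES:
            raise LabelFormatError(lineno, f"unknown class id {class_id}")
        coords = tokens[1:]
        if len(coords) % 2 != 0:
            raise LabelFormatError(lineno, f"odd coordinate count ({len(coords)})")
        if len(coords) < 6:
            raise LabelFormatError(lineno, f"need at least 3 vertices, got {len(coords) // 2}")
        try:
            values = [float(t) for t in coords]
        except ValueError:
            raise LabelFormatError(lineno, "unparseable coordinate") from None
        for v in values:
            if not (0.0 <= v <= 1.0):
                raise LabelFormatError(lineno, f"coordinate {v} outside [0,1]")
        vertices = tuple(zip(values[0::2], values[1::2]))
        annotations.append(PolygonAnnotation(class_id=class_id, vertices=vertices))
    return annotations


def write_labels(annotations: list[PolygonAnnotation]) -> str:
    """Serialize annotations to label-file content (6-decimal coordinates)."""
    lines = []
    for ann in annotations:
        coords = " ".join(
            f"{min(max(c, 0.0), 1.0):.6f}" for xy in ann.vertices for c in xy
        )
        lines.append(f"{ann.class_id} {coords}")
    return "\n".join(lines) + ("\n" if lines else "")


def _points_in_polygon(xs: np.ndarray, ys: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd (crossing number) point-in-polygon test, vectorized over points.

    A point exactly on a horizontal upper/right edge falls outside, matching
    the half-open convention that tiles adjacent polygons without overlap.
    """
    px, py = poly[:, 0], poly[:, 1]
    qx, qy = np.roll(px, -1), np.roll(py, -1)
    inside = np.zeros(xs.shape, dtype=bool)
    for x0, y0, x1, y1 in zip(px, py, qx, qy):
        crosses = (y0 > ys) != (y1 > ys)
        if not crosses.any():
            continue
        # x coordinate where the edge crosses the scanline through each point
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x0 + (ys - y0) * (x1 - x0) / (y1 - y0)
        inside ^= crosses & (xs < xint)
    return inside


def rasterize(
    annotation: PolygonAnnotation, image_width: int, image_height: int,
    instance_id: int = 0, confidence: float = 1.0,
) -> InstanceMask:
    """Rasterize a polygon annotation to a binary instance mask.

    Foreground pixels are those whose centers (integer coordinates) lie inside
    the polygon under the even-odd rule.  A polygon enclosing no pixel center
    yields an empty-flagged mask rather than an error.
    """
    poly = annotation.pixel_vertices(image_width, image_height)
    raster = np.zeros((image_height, image_width), dtype=bool)
    x_lo = max(int(np.floor(poly[:, 0].min())), 0)
    x_hi = min(int(np.ceil(poly[:, 0].max())) + 1, image_width)
    y_lo = max(int(np.floor(poly[:, 1].min())), 0)
    y_hi = min(int(np.ceil(poly[:, 1].max())) + 1, image_height)
    if x_lo < x_hi and y_lo < y_hi:
        ys, xs = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        raster[y_lo:y_hi, x_lo:x_hi] = _points_in_polygon(
            xs.astype(float), ys.astype(float), poly
        )
    return InstanceMask(
        raster=raster,
        class_id=annotation.class_id,
        instance_id=instance_id,
        confidence=confidence,
        empty=not raster.any(),
    )


def rasterize_all(
    annotations: list[PolygonAnnotation], image_width: int, image_height: int
) -> list[InstanceMask]:
    """Rasterize a label file's annotations; instance ids follow file order from 0."""
    return [
        rasterize(ann, image_width, image_height, instance_id=i)
        for i, ann in enumerate(annotations)
    ]


def save_mask_png(mask: InstanceMask, path) -> None:
    """Write a mask as a single-channel PNG (0 background / 255 foreground)."""
    Image.fromarray(mask.raster.astype(np.uint8) * 255, mode="L").save(path)


def load_mask_png(path, class_id: int, instance_id: int, confidence: float = 1.0) -> InstanceMask:
    """Load a single-channel PNG into an InstanceMask (any nonzero pixel is foreground)."""
    raster = np.asarray(Image.open(path).convert("L")) > 0
    return InstanceMask(
        raster=raster, class_id=class_id, instance_id=instance_id,
        confidence=confidence, empty=not raster.any(),
    )
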