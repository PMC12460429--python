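"""Picking-point localization on a matched stem mask.

Pipeline per stem: crop a padded region of interest (ROI) around the mask,
binarize, apply morphological opening to remove speckle and false
connections, thin the result to a 1-pixel-wide skeleton, take the longest
geodesic path between skeleton endpoints as the centerline, and select the
pixel at half its cumulative arc length as the picking point.  The point is
translated back to full-image coordinates through the recorded ROI offset.

Diagonal skeleton steps contribute sqrt(2) to arc length, axis steps 1.  On
even-length ties the pixel at the smaller path index is chosen, so results
are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import thin

from .labelio import InstanceMask

SQRT2 = math.sqrt(2.0)


@dataclass
class Skeleton:
    """Thinned stem centerline: all skeleton pixels plus the selected simple path."""

    pixels: set[tuple[int, int]]  # (x, y) in ROI coordinates
    path: list[tuple[int, int]]  # ordered along the centerline
    arc_length: float
    roi_offset: tuple[int, int]


@dataclass(frozen=True)
class PickPoint:
    """Pixel where the harvester should cut, in full-image coordinates."""

    xy_image: tuple[int, int]
    stem_id: int
    fruit_id: int | None
    arc_position: float  # fraction of the centerline arc length, ~0.5


def cross_kernel(size: int = 3) -> np.ndarray:
    """Elliptical (cross-shaped at 3x3) structuring element of odd side length."""
    if size < 1 or size % 2 == 0:
        raise ValueError("kernel size must be a positive odd integer")
    if size == 1:
        return np.ones((1, 1), dtype=bool)
    r = size // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (xx / r) ** 2 + (yy / r) ** 2 <= 1.0 + 1e-9


def extract_roi(stem: InstanceMask, padding: int = 2) -> tuple[np.ndarray, tuple[int, int]]:
    """Crop the stem's bounding box dilated by `padding`, clipped to the image.

    Returns the binary ROI raster and the (x, y) offset of its origin in image
    coordinates, which inverts the crop exactly.
    """
    ys, xs = np.nonzero(stem.raster)
    if ys.size == 0:
        raise ValueError(f"stem mask {stem.instance_id} is empty")
    h, w = stem.raster.shape
    y0 = max(int(ys.min()) - padding, 0)
    y1 = min(int(ys.max()) + padding + 1, h)
    x0 = max(int(xs.min()) - padding, 0)
    x1 = min(int(xs.max()) + padding + 1, w)
    return stem.raster[y0:y1, x0:x1].copy(), (x0, y0)


def morph_open(roi: np.ndarray, kernel: np.ndarray | None = None) -> np.ndarray:
    """Binary opening (erosion then dilation) with the given structuring element."""
    if kernel is None:
        kernel = cross_kernel(3)
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        return roi.copy()
    return ndimage.binary_opening(roi, structure=kernel)


def _neighbors(p: tuple[int, int], pixels: set[tuple[int, int]]):
    x, y = p
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            if dx == 0 and dy == 0:
                continue
            q = (x + dx, y + dy)
            if q in pixels:
                yield q


def _skeleton_graph(pixels: set[tuple[int, int]]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(pixels)
    for p in pixels:
        for q in _neighbors(p, pixels):
            w = 1.0 if p[0] == q[0] or p[1] == q[1] else SQRT2
            g.add_edge(p, q, weight=w)
    return g


def _path_arc_length(path: list[tuple[int, int]]) -> float:
    return sum(
        1.0 if p[0] == q[0] or p[1] == q[1] else SQRT2 for p, q in zip(path, path[1:])
    )


def thin_skeleton(roi: np.ndarray, roi_offset: tuple[int, int] = (0, 0)) -> Skeleton:
    """Thin a binary ROI to a skeleton and extract its longest centerline path.

    The raster is thinned iteratively until 1 pixel wide (no full 2x2
    foreground block survives).  Branches are handled by restricting to the
    largest 8-connected skeleton component and taking the longest geodesic
    path between its endpoints (pixels with exactly one skeleton neighbor) —
    small spurs lose to the main axis.  Components that are single pixels or
    closed loops fall back to a diameter path from the lexicographically
    smallest pixel.
    """
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty raster: nothing to thin (opening may have removed the stem; try a smaller kernel)")
    sk = thin(roi)
    labels, n = ndimage.label(sk, structure=np.ones((3, 3), dtype=int))
    if n > 1:
        sizes = ndimage.sum_labels(sk, labels, index=np.arange(1, n + 1))
        keep = int(np.argmax(sizes)) + 1
        sk = labels == keep
    ys, xs = np.nonzero(sk)
    pixels = set(zip(xs.tolist(), ys.tolist()))
    if len(pixels) == 1:
        p = next(iter(pixels))
        return Skeleton(pixels=pixels, path=[p], arc_length=0.0, roi_offset=roi_offset)

    g = _skeleton_graph(pixels)
    endpoints = sorted(p for p in pixels if g.degree(p) == 1)
    if not endpoints:
        # closed loop: fall back to a deterministic double-sweep diameter
        start = min(pixels)
        far1 = max(nx.single_source_dijkstra_path_length(g, start).items(), key=lambda kv: (kv[1], kv[0]))[0]
        endpoints = [far1]
    # longest geodesic path over endpoint pairs
    best_path: list[tuple[int, int]] = [endpoints[0]]
    best_len = -1.0
    for src in endpoints:
        lengths, paths = nx.single_source_dijkstra(g, src)
        candidates = endpoints if len(endpoints) > 1 else list(lengths)
        for dst in candidates:
            if dst == src:
                continue
            if lengths.get(dst, -1.0) > best_len + 1e-12:
                best_len = lengths[dst]
                best_path = paths[dst]
    arc = _path_arc_length(best_path)
    return Skeleton(pixels=pixels, path=best_path, arc_length=arc, roi_offset=roi_offset)


def locate_pick_point(
    skeleton: Skeleton, stem_id: int, fruit_id: int | None = None
) -> PickPoint:
    """Select the centerline pixel at half the cumulative arc length.

    Ties (even pixel counts / equidistant pixels) resolve to the smaller path
    index.  The returned coordinates are in full-image space.
    """
    path = skeleton.path
    if not path:
        raise ValueError("skeleton path is empty")
    cum = [0.0]
    for p, q in zip(path, path[1:]):
        cum.append(cum[-1] + (1.0 if p[0] == q[0] or p[1] == q[1] else SQRT2))
    total = cum[-1]
    target = total / 2.0
    idx = min(range(len(path)), key=lambda i: (abs(cum[i] - target), i))
    x, y = path[idx]
    ox, oy = skeleton.roi_offset
    return PickPoint(
        xy_image=(x + ox, y + oy),
        stem_id=stem_id,
        fruit_id=fruit_id,
        arc_position=(cum[idx] / total) if total > 0 else 0.5,
    )


def pick_point_for_stem(
    stem: InstanceMask,
    stem_id: int | None = None,
    fruit_id: int | None = None,
    kernel_size: int = 3,
    padding: int = 2,
) -> PickPoint:
    """End-to-end localization: ROI -> opening -> thinning -> arc-length midpoint."""
    roi, offset = extract_roi(stem, padding=padding)
    opened = morph_open(roi, cross_kernel(kernel_size))
    if not opened.any():
        raise ValueError(
            f"opening with a {kernel_size}x{kernel_size} kernel removed the whole stem; use a smaller kernel"
        )
    skeleton = thin_skeleton(opened, roi_offset=offset)
    sid = stem.instance_id if stem_id is None else stem_id
    return locate_pick_point(skeleton, stem_id=sid, fruit_id=fruit_id)


__all__ = [
    "Skeleton",
    "PickPoint",
    "cross_kernel",
    "extract_roi",
    "morph_open",
    "thin_skeleton",
    "locate_pick_point",
    "pick_point_for_stem",
]
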