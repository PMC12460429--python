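"""Geometric fruit-to-stem matching under a centroid-radius distance constraint.

Each segmented stem region is summarized by a straight line fitted to its
contour (or all its pixels).  For every fruit, the Euclidean distance d_i from
the fruit centroid (x_c, y_c) to each fitted stem line y = a_i x + b_i is

    d_i = |a_i x_c - y_c + b_i| / sqrt(a_i^2 + 1)

and the nearest stem l_min = argmin_i d_i is the candidate.  The candidate is
accepted as the target stem only when its distance d_1 = min_i d_i is smaller
than the fruit's own centroid-to-contour radius d, i.e. d_1 < d.  The radius
defaults to the *maximum* centroid-to-boundary distance (the fruit's full
physical extent); the minimum is available as an option.

Lines are represented by an anchor point plus a unit direction so that
near-vertical stems — the common case for hanging fruit — are not singular;
the slope/intercept view is derived from that form where it exists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .labelio import InstanceMask

_TIE_EPS = 1e-9


@dataclass(frozen=True)
class FittedLine:
    """A 2-D line as anchor + unit direction, with an optional slope/intercept view."""

    anchor: tuple[float, float]
    direction: tuple[float, float]

    def __post_init__(self):
        norm = math.hypot(*self.direction)
        if not math.isclose(norm, 1.0, abs_tol=1e-9):
            raise ValueError("direction must be a unit vector")

    @property
    def slope_intercept(self) -> tuple[float, float] | None:
        """(a, b) of y = a x + b, or None for a vertical line."""
        ux, uy = self.direction
        if ux == 0.0:
            return None
        a = uy / ux
        b = self.anchor[1] - a * self.anchor[0]
        return a, b

    @classmethod
    def from_slope_intercept(cls, a: float, b: float) -> "FittedLine":
        norm = math.hypot(1.0, a)
        return cls(anchor=(0.0, b), direction=(1.0 / norm, a / norm))

    @classmethod
    def vertical(cls, x0: float) -> "FittedLine":
        return cls(anchor=(x0, 0.0), direction=(0.0, 1.0))


@dataclass
class FruitFeature:
    """Centroid/boundary summary of one fruit mask used by the matcher."""

    instance_id: int
    centroid: tuple[float, float]
    boundary: np.ndarray  # (n, 2) pixel coordinates (x, y) of the outer contour
    pixel_count: int
    r_min: float
    r_max: float


@dataclass
class MatchResult:
    """Per-fruit matching outcome: candidate distances, best stem and the d1 < d verdict."""

    fruit_id: int
    candidate_distances: dict[int, float]
    best_stem: int | None
    d1: float | None
    threshold: float
    matched: bool
    excluded_stems: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "fruit_id": self.fruit_id,
            "candidate_distances": {str(k): v for k, v in self.candidate_distances.items()},
            "best_stem": self.best_stem,
            "d1": self.d1,
            "threshold": self.threshold,
            "matched": self.matched,
        }


def _mask_points(mask: InstanceMask) -> np.ndarray:
    ys, xs = np.nonzero(mask.raster)
    return np.column_stack([xs, ys]).astype(float)


def boundary_points(mask: InstanceMask) -> np.ndarray:
    """Outer contour pixels: foreground pixels with a 4-adjacent background pixel.

    This inner boundary forms an 8-connected curve around each component.
    """
    r = mask.raster
    padded = np.pad(r, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    edge = r & ~interior
    ys, xs = np.nonzero(edge)
    return np.column_stack([xs, ys]).astype(float)


def fruit_features(fruit: InstanceMask) -> FruitFeature:
    """Compute centroid, outer boundary and centroid-to-boundary radii of a fruit mask.

    The centroid is the arithmetic mean of the M foreground pixel coordinates;
    r_min/r_max are the min/max Euclidean distances from the centroid to the
    boundary points.
    """
    pts = _mask_points(fruit)
    if pts.shape[0] == 0:
        raise ValueError(f"fruit mask {fruit.instance_id} is empty")
    centroid = pts.mean(axis=0)
    bnd = boundary_points(fruit)
    dists = np.hypot(bnd[:, 0] - centroid[0], bnd[:, 1] - centroid[1])
    return FruitFeature(
        instance_id=fruit.instance_id,
        centroid=(float(centroid[0]), float(centroid[1])),
        boundary=bnd,
        pixel_count=pts.shape[0],
        r_min=float(dists.min()),
        r_max=float(dists.max()),
    )


def fit_points_line(points: np.ndarray, method: str = "tls") -> FittedLine:
    """Fit a line to (x, y) points by ordinary (vertical residual) or total least squares."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if pts.shape[0] < 2:
        raise ValueError("need at least 2 distinct points to fit a line")
    x, y = pts[:, 0], pts[:, 1]
    if method == "ols":
        if np.ptp(x) == 0.0:
            raise ValueError(
                "ordinary least squares is undefined for a vertical point set; use method='tls'"
            )
        a, b = np.polyfit(x, y, 1)
        return FittedLine.from_slope_intercept(float(a), float(b))
    if method == "tls":
        centered = pts - pts.mean(axis=0)
        # principal axis = right singular vector of the centered point cloud
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        ux, uy = vt[0]
        if ux < 0 or (ux == 0 and uy < 0):  # canonical orientation
            ux, uy = -ux, -uy
        mean = pts.mean(axis=0)
        return FittedLine(anchor=(float(mean[0]), float(mean[1])), direction=(float(ux), float(uy)))
    raise ValueError(f"unknown fit method {method!r}")


def fit_stem_line(stem: InstanceMask, mode: str = "contour", method: str = "tls") -> FittedLine:
    """Fit a straight line to a stem mask's contour points (or all pixels)."""
    if mode == "contour":
        pts = boundary_points(stem)
    elif mode == "all_pixels":
        pts = _mask_points(stem)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return fit_points_line(pts, method=method)


def point_line_distance(point: tuple[float, float], line: FittedLine) -> float:
    """Orthogonal distance from a point to an infinite line.

    Equals |a x - y + b| / sqrt(a^2 + 1) whenever the slope form exists.
    """
    px, py = point
    ax, ay = line.anchor
    ux, uy = line.direction
    # rejection of (p - anchor) from the unit direction
    rx, ry = px - ax, py - ay
    t = rx * ux + ry * uy
    return math.hypot(rx - t * ux, ry - t * uy)


def match_scene(
    fruits: list[FruitFeature],
    stems: list[tuple[int, FittedLine]],
    radius_mode: str = "max",
) -> list[MatchResult]:
    """Match every fruit to its nearest stem line under the d1 < d constraint.

    Each fruit is handled independently: distances d_i to every stem line are
    computed, the argmin (ties broken toward the lowest stem id) is the
    candidate, and the fruit is matched iff d1 < d where d is the fruit's
    centroid-to-boundary radius (r_max by default, r_min with
    radius_mode="min").  A stem may be the best candidate for several fruits;
    with no stems every fruit is unmatched with an empty candidate map.
    """
    if radius_mode not in ("max", "min"):
        raise ValueError(f"unknown radius_mode {radius_mode!r}")
    results = []
    for fruit in fruits:
        distances = {
            stem_id: point_line_distance(fruit.centroid, line) for stem_id, line in stems
        }
        threshold = fruit.r_max if radius_mode == "max" else fruit.r_min
        if distances:
            d1 = min(distances.values())
            best = min(sid for sid, d in distances.items() if d <= d1 + _TIE_EPS)
            matched = d1 < threshold
        else:
            d1, best, matched = None, None, False
        results.append(
            MatchResult(
                fruit_id=fruit.instance_id,
                candidate_distances=distances,
                best_stem=best if matched or best is not None else None,
                d1=d1,
                threshold=threshold,
                matched=matched,
            )
        )
    return results
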