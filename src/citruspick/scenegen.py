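"""Seeded synthetic orchard scenes for exercising the matching and
localization stages without field imagery.

Each scene is a set of binary instance masks (citrus fruits and the short
stem segments near the fruit junction) plus exact ground truth: fruit
centroids, stem axis polylines, fruit-to-stem associations and the picking
point at the arc-length midpoint of each stem axis.  The generator reproduces
the topologies the matcher must disambiguate — one fruit per stem, one stem
shared by two fruits, and fruitless stems — and three occlusion regimes:
none (fully visible), mild (every instance keeps more than 60% of its pixel
area) and moderate (every instance keeps between 30% and 60%).

Fruits are near-circular ellipses (axis ratio 0.85–1.0); stems are
constant-thickness segments inclined 30°–60° from vertical, attached at the
fruit boundary and pointing radially away from the fruit centre, mirroring
how citrus hangs.  Only the stem segment near the fruit is rendered, the way
the short annotation windows are drawn in practice.  Scene i of a batch uses
an RNG seeded from (global seed, i) so every scene is independently
reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.measure import find_contours
from scipy import ndimage

from .labelio import (
    FRUIT_CLASS,
    STEM_CLASS,
    InstanceMask,
    PolygonAnnotation,
    save_mask_png,
    write_labels,
)

OCCLUSION_LEVELS = ("none", "mild", "moderate")
# visibility band per occlusion level: (hard lo, hard hi, target lo, target hi)
_BANDS = {
    "none": (1.0, 1.0, 1.0, 1.0),
    "mild": (0.60, 1.0, 0.68, 0.92),
    "moderate": (0.30, 0.60, 0.35, 0.58),
}
_MAX_RETRIES = 100


class PlacementError(RuntimeError):
    """Raised when a scene cannot be laid out within the retry budget."""


@dataclass(frozen=True)
class SceneConfig:
    """Generator parameters; defaults describe a 640x640 orchard crop."""

    image_width: int = 640
    image_height: int = 640
    n_fruits: int = 3
    fruit_radius_range: tuple[float, float] = (20.0, 36.0)
    stem_length_range: tuple[float, float] = (40.0, 80.0)
    stem_thickness_range: tuple[float, float] = (3.0, 7.0)
    stem_inclination_range: tuple[float, float] = (30.0, 60.0)
    p_shared_stem: float = 0.2
    p_fruitless_stem: float = 0.15
    occlusion_level: str = "none"
    stem_bend_max_deg: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("fruit_radius_range", "stem_length_range",
                     "stem_thickness_range", "stem_inclination_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got {(lo, hi)}")
        for name in ("p_shared_stem", "p_fruitless_stem"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {p}")
        if self.occlusion_level not in OCCLUSION_LEVELS:
            raise ValueError(f"occlusion_level must be one of {OCCLUSION_LEVELS}")
        if self.n_fruits < 0:
            raise ValueError("n_fruits must be >= 0")
        if self.image_width < 64 or self.image_height < 64:
            raise ValueError("image must be at least 64x64")
        if not (0.0 <= self.stem_bend_max_deg <= 15.0):
            raise ValueError("stem_bend_max_deg must be in [0, 15]")


@dataclass
class FruitTruth:
    instance_id: int
    centroid: tuple[float, float]  # (x, y), mean of full-mask pixels
    mask: np.ndarray  # visible raster
    full_mask: np.ndarray  # unoccluded raster
    radius: float


@dataclass
class StemTruth:
    instance_id: int
    mask: np.ndarray
    full_mask: np.ndarray
    axis: list[tuple[float, float]]  # polyline endpoints, fruit end first


@dataclass
class SceneTruth:
    image_width: int
    image_height: int
    fruits: list[FruitTruth]
    stems: list[StemTruth]
    associations: dict[int, int | None]  # fruit id -> stem id
    true_pick_points: dict[int, tuple[int, int]]  # stem id -> (x, y)
    visibility: dict[str, float] = field(default_factory=dict)  # "fruit_0" etc.

    def to_json_dict(self) -> dict:
        return {
            "image_width": self.image_width,
            "image_height": self.image_height,
            "fruits": [
                {"id": f.instance_id, "centroid": list(f.centroid), "radius": f.radius}
                for f in self.fruits
            ],
            "stems": [
                {"id": s.instance_id, "axis": [list(p) for p in s.axis]}
                for s in self.stems
            ],
            "associations": {str(k): v for k, v in self.associations.items()},
            "true_pick_points": {str(k): list(v) for k, v in self.true_pick_points.items()},
            "visibility": dict(self.visibility),
        }


def _disk_footprint(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return xx * xx + yy * yy <= radius * radius


def _render_fruit(cx, cy, rx, ry, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_ellipse(cy, cx, ry, rx, shape=shape)
    mask[rr, cc] = True
    return mask


def _render_stem(axis: list[tuple[float, float]], thickness: float, shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    for (x0, y0), (x1, y1) in zip(axis, axis[1:]):
        rr, cc = draw_line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
        keep = (rr >= 0) & (rr < shape[0]) & (cc >= 0) & (cc < shape[1])
        mask[rr[keep], cc[keep]] = True
    r = max(int(round((thickness - 1) / 2)), 1)
    return ndimage.binary_dilation(mask, structure=_disk_footprint(r))


def _axis_midpoint(axis: list[tuple[float, float]]) -> tuple[float, float]:
    """Arc-length midpoint of a polyline."""
    segs = list(zip(axis, axis[1:]))
    lengths = [math.dist(p, q) for p, q in segs]
    total = sum(lengths)
    target = total / 2.0
    acc = 0.0
    for (p, q), ln in zip(segs, lengths):
        if acc + ln >= target:
            t = (target - acc) / ln if ln > 0 else 0.0
            return (p[0] + t * (q[0] - p[0]), p[1] + t * (q[1] - p[1]))
        acc += ln
    return axis[-1]


def _line_point_distance(p0, u, point) -> float:
    rx, ry = point[0] - p0[0], point[1] - p0[1]
    t = rx * u[0] + ry * u[1]
    return math.hypot(rx - t * u[0], ry - t * u[1])


def _stem_axis(p_start, u, length, bend_deg, rng) -> list[tuple[float, float]]:
    if bend_deg <= 0:
        p_end = (p_start[0] + length * u[0], p_start[1] + length * u[1])
        return [p_start, p_end]
    phi = math.radians(rng.uniform(-bend_deg, bend_deg))
    half = length / 2.0
    mid = (p_start[0] + half * u[0], p_start[1] + half * u[1])
    c, s = math.cos(phi), math.sin(phi)
    v = (u[0] * c - u[1] * s, u[0] * s + u[1] * c)
    end = (mid[0] + half * v[0], mid[1] + half * v[1])
    return [p_start, mid, end]


def _sample_direction(config: SceneConfig, rng) -> tuple[float, float]:
    """Upward unit vector inclined theta in [lo,hi] degrees from vertical."""
    theta = math.radians(rng.uniform(*config.stem_inclination_range))
    side = 1.0 if rng.random() < 0.5 else -1.0
    return (side * math.sin(theta), -math.cos(theta))


def _occlude_instance(full_mask: np.ndarray, level: str, rng) -> tuple[np.ndarray, float]:
    """Overlay leaf-like elliptical occluders until visibility enters the band."""
    lo, hi, tlo, thi = _BANDS[level]
    if level == "none":
        return full_mask.copy(), 1.0
    area0 = int(full_mask.sum())
    visible = full_mask.copy()
    target = rng.uniform(tlo, thi)
    retries = 0
    while visible.sum() / area0 > target:
        ratio = visible.sum() / area0
        ys, xs = np.nonzero(visible)
        i = rng.integers(len(ys))
        cy, cx = int(ys[i]), int(xs[i])
        # leaf sized to remove roughly 5-10% of the original area per step
        frac = rng.uniform(0.05, 0.10)
        a = math.sqrt(frac * area0 / math.pi) * rng.uniform(1.0, 1.6)
        b = frac * area0 / (math.pi * a)
        rot = rng.uniform(0, math.pi)
        occ = np.zeros_like(full_mask)
        rr, cc = draw_ellipse(cy, cx, max(a, 1.0), max(b, 1.0), shape=full_mask.shape, rotation=rot)
        occ[rr, cc] = True
        new_visible = visible & ~occ
        new_ratio = new_visible.sum() / area0
        if new_ratio < lo + 0.02:
            retries += 1
            if retries > _MAX_RETRIES:
                raise PlacementError(
                    f"could not reach the {level!r} visibility band "
                    f"(stuck at {ratio:.2f}) within {_MAX_RETRIES} occluder retries"
                )
            continue
        visible = new_visible
    ratio = float(visible.sum() / area0)
    assert lo < ratio <= hi or (level == "mild" and ratio > lo)
    return visible, ratio


def _place_group(config, rng, existing_fruits, existing_stems, n_in_group):
    """Sample one stem plus its 1 or 2 fruits, honouring separation constraints.

    existing_fruits: list of (center, r_max_estimate); existing_stems: list of
    (p0, u).  Separation rules keep every fruit centroid farther than its own
    radius from every *other* stem's infinite line, so ground-truth
    associations are geometrically unambiguous.
    """
    W, H = config.image_width, config.image_height
    r_hi = config.fruit_radius_range[1]
    len_hi = config.stem_length_range[1]
    margin = r_hi * (2 if n_in_group == 2 else 1) + len_hi + 8
    if 2 * margin >= min(W, H):
        raise PlacementError(
            f"image {W}x{H} too small for fruits of radius up to {r_hi} with "
            f"stems up to {len_hi} px; enlarge the image or shrink the ranges"
        )
    for _ in range(_MAX_RETRIES):
        u = _sample_direction(config, rng)
        length = rng.uniform(*config.stem_length_range)
        thickness = rng.uniform(*config.stem_thickness_range)
        p_start = (rng.uniform(margin, W - margin), rng.uniform(margin, H - margin))
        fruits = []
        # attach at 0.85*r - 2 px from the centre: inside the boundary for any
        # ellipse axis ratio in [0.85, 1], so stem and fruit always touch
        if n_in_group == 1:
            r = rng.uniform(*config.fruit_radius_range)
            depth = 0.85 * r - 2.0
            center = (p_start[0] - depth * u[0], p_start[1] - depth * u[1])
            fruits.append((center, r))
        else:
            # shared stem: two fruits flanking the axis (one-stem-two-fruits case)
            n = (-u[1], u[0])
            for sign in (1.0, -1.0):
                r = rng.uniform(*config.fruit_radius_range)
                off = 0.35 * r
                along = math.sqrt(max((0.85 * r - 2.0) ** 2 - off ** 2, 1.0))
                center = (
                    p_start[0] - along * u[0] + sign * off * n[0],
                    p_start[1] - along * u[1] + sign * off * n[1],
                )
                fruits.append((center, r))
        ok = True
        # fruits well separated from existing fruits
        for center, r in fruits:
            for c2, r2 in existing_fruits:
                if math.dist(center, c2) < r + r2 + 20:
                    ok = False
        # new fruits far from existing stem lines; existing fruits far from the new line
        for center, r in fruits:
            for p0, u0 in existing_stems:
                if _line_point_distance(p0, u0, center) < 1.3 * r + 8:
                    ok = False
        for c2, r2 in existing_fruits:
            if _line_point_distance(p_start, u, c2) < 1.3 * r2 + 8:
                ok = False
        if n_in_group == 2:
            d0 = math.dist(fruits[0][0], fruits[1][0])
            if d0 < 0.4 * (fruits[0][1] + fruits[1][1]):
                ok = False
        if ok:
            return p_start, u, length, thickness, fruits
    raise PlacementError(
        "could not place a fruit/stem group without violating the separation "
        f"constraints after {_MAX_RETRIES} retries; reduce n_fruits or enlarge the image"
    )


def _layout_scene(config, rng, groups, n_fruitless):
    """Place every stem and fruit of a scene; raise PlacementError on deadlock.

    Returns (stem_specs, fruit_specs): stem_specs[i] = (p_start, u, length,
    thickness); fruit_specs[j] = (center, major_radius, stem_id).
    """
    placed_fruits: list[tuple[tuple[float, float], float]] = []
    placed_stems: list[tuple[tuple[float, float], tuple[float, float]]] = []
    stem_specs = []
    fruit_specs = []
    for stem_id, n_in_group in enumerate(groups):
        p_start, u, length, thickness, fruits = _place_group(
            config, rng, placed_fruits, placed_stems, n_in_group
        )
        stem_specs.append((p_start, u, length, thickness))
        placed_stems.append((p_start, u))
        for center, r in fruits:
            fruit_specs.append((center, r, stem_id))
            placed_fruits.append((center, r))
    for _ in range(n_fruitless):
        for attempt in range(_MAX_RETRIES + 1):
            if attempt == _MAX_RETRIES:
                raise PlacementError(
                    "could not place a fruitless stem far enough from every fruit "
                    f"centroid after {_MAX_RETRIES} retries"
                )
            u = _sample_direction(config, rng)
            length = rng.uniform(*config.stem_length_range)
            thickness = rng.uniform(*config.stem_thickness_range)
            m = config.stem_length_range[1] + 8
            p0 = (
                rng.uniform(m, config.image_width - m),
                rng.uniform(m, config.image_height - m),
            )
            # must not be mistakable for any fruit's stem: its line stays
            # outside every fruit's matching radius
            if all(
                _line_point_distance(p0, u, c) > 1.5 * r + 8 for c, r in placed_fruits
            ) and all(
                math.dist(p0, c) > r + config.stem_length_range[1]
                for c, r in placed_fruits
            ):
                break
        stem_specs.append((p0, u, length, thickness))
        placed_stems.append((p0, u))
    return stem_specs, fruit_specs


def generate_scene(config: SceneConfig) -> tuple[list[InstanceMask], SceneTruth]:
    """Render one seeded scene: instance masks plus exact ground truth.

    Deterministic for a fixed config (including its seed): two calls return
    bit-identical rasters and truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = (config.image_height, config.image_width)

    # group fruits into one-per-stem or two-per-stem (shared) clusters
    groups: list[int] = []
    remaining = config.n_fruits
    while remaining > 0:
        if remaining >= 2 and rng.random() < config.p_shared_stem:
            groups.append(2)
            remaining -= 2
        else:
            groups.append(1)
            remaining -= 1
    n_fruitless = int(rng.random() < config.p_fruitless_stem)

    # lay out the whole scene first (retrying the full layout when a late
    # group cannot fit around the earlier ones), then render
    stem_specs, fruit_specs = None, None
    for _ in range(_MAX_RETRIES):
        try:
            stem_specs, fruit_specs = _layout_scene(config, rng, groups, n_fruitless)
            break
        except PlacementError:
            continue
    if stem_specs is None:
        raise PlacementError(
            f"could not lay out {config.n_fruits} fruits in a "
            f"{config.image_width}x{config.image_height} image within "
            f"{_MAX_RETRIES} whole-scene retries; reduce n_fruits or enlarge the image"
        )

    fruit_truths: list[FruitTruth] = []
    stem_truths: list[StemTruth] = []
    associations: dict[int, int | None] = {}
    pick_points: dict[int, tuple[int, int]] = {}

    for stem_id, (p_start, u, length, thickness) in enumerate(stem_specs):
        axis = _stem_axis(p_start, u, length, config.stem_bend_max_deg, rng)
        stem_mask = _render_stem(axis, thickness, shape)
        mid = _axis_midpoint(axis)
        stem_truths.append(
            StemTruth(instance_id=stem_id, mask=stem_mask, full_mask=stem_mask, axis=axis)
        )
        pick_points[stem_id] = (int(round(mid[0])), int(round(mid[1])))
    for fruit_id, (center, r, stem_id) in enumerate(fruit_specs):
        q = rng.uniform(0.85, 1.0)
        fmask = _render_fruit(center[0], center[1], r, r * q, shape)
        ys, xs = np.nonzero(fmask)
        centroid = (float(xs.mean()), float(ys.mean()))
        fruit_truths.append(
            FruitTruth(
                instance_id=fruit_id, centroid=centroid, mask=fmask,
                full_mask=fmask, radius=r,
            )
        )
        associations[fruit_id] = stem_id

    # occlusion overlay, per instance
    visibility: dict[str, float] = {}
    for f in fruit_truths:
        f.mask, ratio = _occlude_instance(f.full_mask, config.occlusion_level, rng)
        visibility[f"fruit_{f.instance_id}"] = ratio
    for s in stem_truths:
        s.mask, ratio = _occlude_instance(s.full_mask, config.occlusion_level, rng)
        visibility[f"stem_{s.instance_id}"] = ratio

    masks = [
        InstanceMask(raster=f.mask, class_id=FRUIT_CLASS, instance_id=f.instance_id)
        for f in fruit_truths
    ] + [
        InstanceMask(raster=s.mask, class_id=STEM_CLASS, instance_id=s.instance_id)
        for s in stem_truths
    ]
    truth = SceneTruth(
        image_width=config.image_width,
        image_height=config.image_height,
        fruits=fruit_truths,
        stems=stem_truths,
        associations=associations,
        true_pick_points=pick_points,
        visibility=visibility,
    )
    return masks, truth


def scene_seed(global_seed: int, index: int) -> int:
    """Per-scene seed derived from (global seed, scene index); < 2**31."""
    return int(np.random.SeedSequence([global_seed, index]).generate_state(1)[0] % (2**31))


def generate_batch(
    config: SceneConfig, n_scenes: int, global_seed: int
) -> list[tuple[list[InstanceMask], SceneTruth]]:
    """Generate n independent scenes, scene i seeded from (global_seed, i)."""
    out = []
    for i in range(n_scenes):
        cfg = SceneConfig(**{**asdict(config), "seed": scene_seed(global_seed, i)})
        out.append(generate_scene(cfg))
    return out


def mask_to_annotation(mask: InstanceMask, max_vertices: int = 48) -> PolygonAnnotation | None:
    """Trace a mask's outer contour into a normalized polygon annotation."""
    contours = find_contours(mask.raster.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)  # (row, col)
    step = max(len(contour) // max_vertices, 1)
    pts = contour[::step]
    if len(pts) < 3:
        return None
    h, w = mask.raster.shape
    vertices = tuple(
        (min(max(float(c) / w, 0.0), 1.0), min(max(float(r) / h, 0.0), 1.0))
        for r, c in pts
    )
    return PolygonAnnotation(class_id=mask.class_id, vertices=vertices)


def write_scene(out_dir: Path, masks: list[InstanceMask], truth: SceneTruth) -> None:
    """Write one scene: mask PNGs, a polygon label TXT and the truth JSON."""
    out_dir = Path(out_dir)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    annotations = []
    for m in masks:
        cls = "fruit" if m.class_id == FRUIT_CLASS else "stem"
        save_mask_png(m, out_dir / "masks" / f"{cls}_{m.instance_id:03d}.png")
        ann = mask_to_annotation(m)
        if ann is not None:
            annotations.append(ann)
    (out_dir / "labels.txt").write_text(write_labels(annotations))
    (out_dir / "truth.json").write_text(json.dumps(truth.to_json_dict(), indent=1))


def split_dataset(scenes: list, ratios: tuple[float, float, float], seed: int):
    """Shuffle and partition scenes into train/val/test by the given ratios.

    Share sizes are floored and remainders go to the largest fractional
    parts (ties to the earlier part); if that leaves a part empty while there
    are at least as many scenes as parts, one item migrates from the largest
    part to each empty one.  The partition is disjoint, exhaustive and
    deterministic under the seed.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    if abs(sum(ratios) - 1.0) > 1e-6:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    n = len(scenes)
    if n < len(ratios):
        raise ValueError(f"need at least {len(ratios)} scenes to split, got {n}")
    shares = [n * r for r in ratios]
    sizes = [int(math.floor(s)) for s in shares]
    leftovers = n - sum(sizes)
    fracs = sorted(
        range(len(ratios)), key=lambda i: (-(shares[i] - sizes[i]), i)
    )
    for i in range(leftovers):
        sizes[fracs[i]] += 1
    # no part may be empty when n >= n_parts
    for i, sz in enumerate(sizes):
        if sz == 0:
            donor = int(np.argmax(sizes))
            sizes[donor] -= 1
            sizes[i] += 1
    order = np.random.default_rng(seed).permutation(n)
    bounds = np.cumsum(sizes)
    idx = [order[: bounds[0]], order[bounds[0] : bounds[1]], order[bounds[1] :]]
    return tuple([scenes[i] for i in part] for part in idx)
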