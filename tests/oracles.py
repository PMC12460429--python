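"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles with explicit loops and its
own arithmetic, deliberately avoiding the code paths (and where possible the
libraries) used by the package itself.
"""

from __future__ import annotations

import math


def shoelace_area(vertices):
    """Polygon area by the shoelace formula."""
    s = 0.0
    n = len(vertices)
    for i in range(n):
        x0, y0 = vertices[i]
        x1, y1 = vertices[(i + 1) % n]
        s += x0 * y1 - x1 * y0
    return abs(s) / 2.0


def perimeter(vertices):
    n = len(vertices)
    return sum(
        math.dist(vertices[i], vertices[(i + 1) % n]) for i in range(n)
    )


def line_distance(anchor, direction, point):
    """Point-to-line distance via the cross-product formula."""
    ax, ay = anchor
    ux, uy = direction
    px, py = point
    return abs((px - ax) * uy - (py - ay) * ux) / math.hypot(ux, uy)


def ols_line(points):
    """Closed-form normal equations for y = a x + b."""
    n = len(points)
    sx = sum(p[0] for p in points)
    sy = sum(p[1] for p in points)
    sxx = sum(p[0] * p[0] for p in points)
    sxy = sum(p[0] * p[1] for p in points)
    denom = n * sxx - sx * sx
    a = (n * sxy - sx * sy) / denom
    b = (sy - a * sx) / n
    return a, b


def brute_force_match(fruits, stems, radius_mode="max"):
    """All-pairs distance table + argmin + d1 < d check, one fruit at a time.

    fruits: list of objects with .instance_id, .centroid, .r_min, .r_max;
    stems: list of (stem_id, anchor, direction).  Returns per fruit a dict
    {fruit_id, best_stem, d1, matched}.
    """
    out = []
    for f in fruits:
        table = {}
        for sid, anchor, direction in stems:
            table[sid] = line_distance(anchor, direction, f.centroid)
        threshold = f.r_max if radius_mode == "max" else f.r_min
        if table:
            d1 = min(table.values())
            best = min(sid for sid, d in table.items() if d <= d1 + 1e-9)
            matched = d1 < threshold
        else:
            d1, best, matched = None, None, False
        out.append(
            {"fruit_id": f.instance_id, "best_stem": best, "d1": d1, "matched": matched}
        )
    return out


def pixel_set_iou(mask_a, mask_b):
    """IoU from explicit pixel coordinate sets."""
    a = {(i, j) for i, row in enumerate(mask_a) for j, v in enumerate(row) if v}
    b = {(i, j) for i, row in enumerate(mask_b) for j, v in enumerate(row) if v}
    union = a | b
    return len(a & b) / len(union) if union else 0.0


def greedy_counts(predictions, truths, iou_threshold):
    """Greedy confidence-descending matching on explicit pixel sets.

    predictions/truths: lists of (class_id, instance_id, confidence, mask)
    and (class_id, mask) respectively, where mask is a nested bool list.
    Returns {class_id: (TP, FP, FN)}.
    """
    def to_set(mask):
        return frozenset(
            (i, j) for i, row in enumerate(mask) for j, v in enumerate(row) if v
        )

    classes = {p[0] for p in predictions} | {t[0] for t in truths}
    result = {}
    for cid in sorted(classes):
        preds = sorted(
            [p for p in predictions if p[0] == cid], key=lambda p: (-p[2], p[1])
        )
        gts = [to_set(t[1]) for t in truths if t[0] == cid]
        used = [False] * len(gts)
        tp = fp = 0
        for _, _, _, pmask in preds:
            pset = to_set(pmask)
            best_iou, best_j = 0.0, -1
            for j, gset in enumerate(gts):
                if used[j]:
                    continue
                union = pset | gset
                iou = len(pset & gset) / len(union) if union else 0.0
                if iou > best_iou:
                    best_iou, best_j = iou, j
            if best_j >= 0 and best_iou >= iou_threshold:
                used[best_j] = True
                tp += 1
            else:
                fp += 1
        fn = used.count(False)
        result[cid] = (tp, fp, fn)
    return result


def staircase_ap(ranked, n_truth):
    """AP by explicitly evaluating max-precision-to-the-right at every recall level.

    Integrates the precision envelope over recall by scanning the recall
    levels reached by the ranking, computing each interpolated precision with
    a fresh inner loop (no cumulative arrays).
    """
    if n_truth == 0:
        return 0.0
    points = []  # (recall, precision) after each prediction
    tp = fp = 0
    for _, is_tp in ranked:
        if is_tp:
            tp += 1
        else:
            fp += 1
        points.append((tp / n_truth, tp / (tp + fp)))
    ap = 0.0
    prev_r = 0.0
    for k, (r, _) in enumerate(points):
        if r <= prev_r:
            continue
        p_interp = max(p for (r2, p) in points if r2 >= r)
        ap += (r - prev_r) * p_interp
        prev_r = r
    return ap


def polyline_arc_midpoint(path):
    """Arc-length midpoint of a pixel path with explicit step accumulation."""
    steps = [0.0]
    for (x0, y0), (x1, y1) in zip(path, path[1:]):
        steps.append(steps[-1] + (1.0 if x0 == x1 or y0 == y1 else math.sqrt(2.0)))
    total = steps[-1]
    best, best_key = 0, (float("inf"), 0)
    for i, s in enumerate(steps):
        key = (abs(s - total / 2.0), i)
        if key < best_key:
            best, best_key = i, key
    return path[best]
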