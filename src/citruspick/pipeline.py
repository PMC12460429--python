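"""End-to-end orchestration: masks -> matching -> picking points -> evaluation.

Consumes scene directories in the layout produced by
:func:`citruspick.scenegen.write_scene` (``masks/*.png``, ``labels.txt``,
``truth.json``), runs the geometric matcher and the skeleton-midpoint
localizer on every scene, and aggregates segmentation metrics and the
picking-point detection rate into a single versioned JSON report.  Every
stage parameter is echoed into the report so a run is reproducible from its
output alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

from . import labelio, matching, metrics, pickpoint
from .labelio import FRUIT_CLASS, STEM_CLASS, InstanceMask

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str | None = None
    pred_dir: str | None = None  # optional model predictions; defaults to the truth masks
    radius_mode: str = "max"
    fit_method: str = "tls"
    fit_mode: str = "contour"
    kernel_size: int = 3
    padding: int = 2
    iou_threshold: float = 0.5
    pick_tolerance: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if not Path(self.input_dir).is_dir():
            raise FileNotFoundError(f"input directory {self.input_dir!r} does not exist")
        if self.radius_mode not in ("max", "min"):
            raise ValueError("radius_mode must be 'max' or 'min'")
        if self.fit_method not in ("tls", "ols"):
            raise ValueError("fit_method must be 'tls' or 'ols'")
        if not (0 < self.iou_threshold <= 1):
            raise ValueError("iou_threshold must be in (0, 1]")
        if self.pick_tolerance <= 0 or self.kernel_size < 1 or self.padding < 0:
            raise ValueError("pick_tolerance, kernel_size, padding out of range")


def load_scene_masks(scene_dir: Path) -> list[InstanceMask]:
    """Load a scene's instance masks from its ``masks/`` directory."""
    masks = []
    for png in sorted((scene_dir / "masks").glob("*.png")):
        cls_name, idx = png.stem.rsplit("_", 1)
        class_id = FRUIT_CLASS if cls_name == "fruit" else STEM_CLASS
        masks.append(labelio.load_mask_png(png, class_id=class_id, instance_id=int(idx)))
    return masks


def process_scene(
    masks: list[InstanceMask], config: PipelineConfig
) -> tuple[list[matching.MatchResult], dict[int, pickpoint.PickPoint]]:
    """Match fruits to stems and localize a picking point on every matched stem."""
    fruits = [m for m in masks if m.class_id == FRUIT_CLASS and not m.empty]
    stems = [m for m in masks if m.class_id == STEM_CLASS and not m.empty]
    features = [matching.fruit_features(f) for f in fruits]
    fitted = []
    for s in stems:
        try:
            fitted.append(
                (s.instance_id, matching.fit_stem_line(s, mode=config.fit_mode, method=config.fit_method))
            )
        except ValueError:
            log.warning("stem %d has too few pixels to fit; excluded", s.instance_id)
    results = matching.match_scene(features, fitted, radius_mode=config.radius_mode)
    matched_stems = {r.best_stem: r.fruit_id for r in results if r.matched}
    points: dict[int, pickpoint.PickPoint] = {}
    for stem in stems:
        if stem.instance_id not in matched_stems:
            continue
        try:
            points[stem.instance_id] = pickpoint.pick_point_for_stem(
                stem,
                fruit_id=matched_stems[stem.instance_id],
                kernel_size=config.kernel_size,
                padding=config.padding,
            )
        except ValueError as exc:
            log.warning("pick-point localization failed for stem %d: %s", stem.instance_id, exc)
    return results, points


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline over every scene directory under the input dir."""
    config.validate()
    root = Path(config.input_dir)
    scene_dirs = sorted(d for d in root.iterdir() if d.is_dir() and (d / "masks").is_dir())
    if not scene_dirs:
        raise FileNotFoundError(f"no inputs: no scene directories under {root}")

    scene_records = []
    detected = 0
    n_truth_points = 0
    agg_counts: dict[int, metrics.ConfusionCounts] = {}
    agg_ranked: dict[int, list[tuple[float, bool]]] = {}
    for scene_dir in scene_dirs:
        t0 = time.perf_counter()
        try:
            masks = load_scene_masks(scene_dir)
            results, points = process_scene(masks, config)
            record = {
                "scene": scene_dir.name,
                "matches": [r.to_dict() for r in results],
                "pick_points": {
                    str(sid): {
                        "xy": list(p.xy_image),
                        "fruit_id": p.fruit_id,
                        "arc_position": p.arc_position,
                    }
                    for sid, p in points.items()
                },
            }
            truth_file = scene_dir / "truth.json"
            if truth_file.is_file():
                truth = json.loads(truth_file.read_text())
                associated = {v for v in truth["associations"].values() if v is not None}
                truth_points = {
                    int(k): tuple(v)
                    for k, v in truth["true_pick_points"].items()
                    if int(k) in associated
                }
                predicted = {sid: p.xy_image for sid, p in points.items()}
                rate = metrics.pick_point_detection_rate(
                    predicted, truth_points, tolerance=config.pick_tolerance
                ) if truth_points else None
                record["pick_point_detection_rate"] = rate
                detected += sum(
                    1
                    for sid, txy in truth_points.items()
                    if sid in predicted
                    and (predicted[sid][0] - txy[0]) ** 2 + (predicted[sid][1] - txy[1]) ** 2
                    <= config.pick_tolerance**2
                )
                n_truth_points += len(truth_points)
                pred_masks = (
                    load_scene_masks(Path(config.pred_dir) / scene_dir.name)
                    if config.pred_dir
                    else masks
                )
                counts, ranked = metrics.match_instances(
                    pred_masks, masks, iou_threshold=config.iou_threshold
                )
                for cid, cc in counts.items():
                    agg = agg_counts.setdefault(cid, metrics.ConfusionCounts(class_id=cid))
                    agg.TP += cc.TP
                    agg.FP += cc.FP
                    agg.FN += cc.FN
                    agg_ranked.setdefault(cid, []).extend(ranked[cid])
            log.info("scene %s processed in %.3fs", scene_dir.name, time.perf_counter() - t0)
            scene_records.append(record)
        except Exception as exc:  # per-scene failures are logged, not fatal
            log.error("skipping scene %s: %s", scene_dir.name, exc)
    if not scene_records:
        raise RuntimeError("no inputs: every scene failed to process")

    report: dict = {
        "schema_version": SCHEMA_VERSION,
        "config": asdict(config),
        "n_scenes": len(scene_records),
        "scenes": scene_records,
    }
    if n_truth_points:
        overall_rate = detected / n_truth_points
        report["pick_point_detection_rate"] = overall_rate
        report["n_truth_points"] = n_truth_points
        if agg_counts:
            aps = {}
            for cid, ranked in agg_ranked.items():
                ranked.sort(key=lambda t: -t[0])
                n_truth = agg_counts[cid].TP + agg_counts[cid].FN
                aps[cid] = metrics.average_precision(ranked, n_truth)
            report["evaluation"] = metrics.summarize(
                agg_counts, aps, pick_point_detection_rate=overall_rate
            ).to_dict()
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
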