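"""End-to-end orchestration: locate -> extract -> triage/segment ->
screen -> cascade identify -> report.

Works over a corpus directory produced by :mod:`dicascade.synthetic`
(PNG images plus a JSON manifest).  Metaphase images whose post-triage
chromosome count falls outside the screening window (46 +/- 3) are
flagged and excluded from the DIC statistics.  The run report is a plain
dict serialised deterministically (sorted keys, rounded floats), so the
same config and seed give byte-identical JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from PIL import Image
from pydantic import BaseModel, Field

from . import cnn as dc_cnn
from .evaluation import ConfusionCounts, metrics, percent
from .extractor import ExtractorParams, extract_foreground, extract_objects
from .locator import LocatorParams, locate_metaphases, screen_spread
from .triage import SegmenterConfig, TriageRule, triage_objects

log = logging.getLogger("dicascade")


class PipelineConfig(BaseModel):
    """Validated configuration; every published constant appears as a
    named key with its published default."""

    input_dir: str = "."
    out_dir: str = "out"
    stage1_model: Optional[str] = None
    stage2_model: Optional[str] = None
    stage1_only: bool = False
    seed: int = 0

    locator_se_radius: int = Field(4, ge=1)
    locator_cleanup_radius: int = Field(4, ge=0)
    locator_highlight_radius: int = Field(12, ge=0)
    locator_min_area: int = Field(200, ge=1)

    nucleus_se_radius: int = Field(36, ge=1)
    median_kernel: int = Field(3, ge=3)

    wh_min: int = 25
    wh_max: int = 65
    ih_max: int = 3
    min_seed_area: int = 150
    seed_method: str = "distance-maxima"

    screen_center: int = 46
    screen_tolerance: int = 3
    tile_size: int = 151
    dic_score_threshold: float = 0.5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls(**(yaml.safe_load(Path(path).read_text()) or {}))

    def locator_params(self) -> LocatorParams:
        return LocatorParams(self.locator_se_radius, self.locator_cleanup_radius,
                             self.locator_highlight_radius, self.locator_min_area)

    def extractor_params(self) -> ExtractorParams:
        return ExtractorParams(self.nucleus_se_radius, self.median_kernel)

    def triage_rule(self) -> TriageRule:
        return TriageRule(self.wh_min, self.wh_max, self.ih_max)

    def segmenter_config(self) -> SegmenterConfig:
        return SegmenterConfig(self.min_seed_area, self.seed_method)


def _round6(x) -> Optional[float]:
    return None if x is None else round(float(x), 6)


def _truth_is_dic(entry: dict, label_mask: np.ndarray, obj) -> Optional[bool]:
    """Majority ground-truth id under a detected mask -> DIC flag."""
    r0, c0, r1, c1 = obj.bbox
    ids = label_mask[r0:r1, c0:c1][obj.mask_crop]
    ids = ids[ids > 0]
    if ids.size == 0:
        return None
    truth_idx = int(np.bincount(ids).argmax()) - 1
    if truth_idx >= len(entry.get("objects", [])):
        return None
    return entry["objects"][truth_idx]["kind"] == "dicentric"


def process_spread(image: np.ndarray, config: PipelineConfig,
                   stage1: Optional[dc_cnn.TrainedModel] = None,
                   stage2: Optional[dc_cnn.TrainedModel] = None):
    """Extract, triage/segment and (when models are given) classify one
    100x metaphase image.  Returns (records, n_chromosome_objects,
    objects); records[i] describes objects[i]."""
    mask = extract_foreground(image, config.extractor_params(), seed=config.seed)
    objects = extract_objects(image, mask, config.extractor_params().background_level)
    objects = triage_objects(objects, config.triage_rule(),
                             config.segmenter_config())
    individuals = [ob for ob in objects if ob.category == "individual"]
    n_chromosomes = sum(1 for ob in objects if ob.category != "impurity")

    records = []
    scores1 = scores2 = None
    if individuals and stage1 is not None:
        tiles = np.stack([
            (dc_cnn.normalize_tile(ob.image_crop, config.tile_size) * 255)
            .astype(np.uint8) for ob in individuals])
        if config.stage1_only or stage2 is None:
            scores1 = dc_cnn.predict(stage1, tiles)
            final = dc_cnn.is_dic(scores1)
            scores2 = np.full(len(tiles), np.nan)
        else:
            final, scores1, scores2 = dc_cnn.cascade_predict(stage1, stage2, tiles)
    else:
        final = np.zeros(len(individuals), dtype=bool)

    it = iter(range(len(individuals)))
    for ob in objects:
        rec = {
            "bbox": [int(v) for v in ob.bbox],
            "area": ob.area, "WH": ob.WH, "IH": ob.IH,
            "category": ob.category,
            "parent_mass_id": ob.parent_mass_id,
            "stage1_score": None, "stage2_score": None,
            "final_label": None,
            "discard_reason": None if ob.category != "impurity" else "impurity-rule",
        }
        if ob.category == "individual":
            i = next(it)
            if scores1 is not None:
                rec["stage1_score"] = _round6(scores1[i])
                s2 = scores2[i]
                rec["stage2_score"] = None if np.isnan(s2) else _round6(s2)
                rec["final_label"] = "DIC" if final[i] else "non-DIC"
        records.append(rec)
    return records, n_chromosomes, objects


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the four pipeline steps over a corpus directory."""
    in_dir = Path(config.input_dir)
    manifest_path = in_dir / "manifest.json"
    manifest = json.loads(manifest_path.read_text()) if manifest_path.exists() else {"images": []}

    stage1 = stage2 = None
    if config.stage1_model:
        stage1 = dc_cnn.TrainedModel.load(config.stage1_model)
        if config.stage2_model and not config.stage1_only:
            stage2 = dc_cnn.TrainedModel.load(config.stage2_model)

    report: dict = {"config_seed": config.seed, "images": [], "objects": {},
                    "screened_out": [], "log": []}
    tp = fp = fn = tn = 0

    for entry in manifest["images"]:
        path = in_dir / entry["path"]
        try:
            image = np.asarray(Image.open(path))
        except OSError:
            log.warning("unreadable image skipped: %s", entry["path"])
            report["log"].append({"image": entry["path"], "event": "unreadable-skip"})
            continue
        if entry.get("magnification") == "10x":
            cands = locate_metaphases(image, config.locator_params())
            report["images"].append({
                "path": entry["path"], "magnification": "10x",
                "n_candidates": len(cands),
                "candidates": [{"centroid": [_round6(c.centroid[0]), _round6(c.centroid[1])],
                                "area": c.area_px} for c in cands]})
            continue
        if "tiles/" in entry["path"]:
            continue
        records, n_chrom, objects = process_spread(image, config, stage1, stage2)
        accepted = screen_spread(n_chrom, config.screen_center, config.screen_tolerance)
        report["images"].append({
            "path": entry["path"], "magnification": "100x",
            "n_objects": len(records), "n_chromosome_objects": n_chrom,
            "screen_accepted": accepted})
        event = "screened" if accepted else "screen-rejected"
        log.info("%s: %d chromosome objects (%s)", entry["path"], n_chrom, event)
        report["log"].append({"image": entry["path"], "event": event,
                              "n_chromosome_objects": n_chrom})
        if not accepted:
            report["screened_out"].append(entry["path"])
        report["objects"][entry["path"]] = records
        if not accepted:
            continue

        label_mask = None
        if entry.get("label_mask"):
            label_mask = np.asarray(Image.open(in_dir / entry["label_mask"]))
        if label_mask is not None and stage1 is not None:
            for ob, rec in zip(objects, records):
                if rec["final_label"] is None:
                    continue
                truth = bool(_truth_is_dic(entry, label_mask, ob))
                pred = rec["final_label"] == "DIC"
                if pred and truth:
                    tp += 1
                elif pred:
                    fp += 1
                elif truth:
                    fn += 1
                else:
                    tn += 1

    if tp + fp + fn + tn > 0:
        counts = ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)
        rep = metrics(counts)
        report["confusion"] = {"TP": tp, "FP": fp, "FN": fn, "TN": tn}
        report["metrics"] = {k: percent(v) for k, v in rep.as_dict().items()}
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, sort_keys=True, indent=1)
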