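"""Width/hole triage of detected objects and watershed mass splitting.

Each detected body is reduced to two morphological features: WH, the
short side of its minimum-area enclosing rectangle, and IH, the number of
enclosed background holes.  The rule table is the published one: an
object with WH < 25 or IH > 3 is an impurity, WH > 65 an adhesive
chromosome mass, anything else an individual chromosome (general
chromosomes have IH 0, dicentrics 1, tricentrics 2; arm crossings can add
one more).  Masses are split by marker-controlled watershed on the
Euclidean distance transform; seed regions smaller than 150 px are
discarded first, which is what keeps the watershed from over-segmenting.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from skimage.morphology import local_maxima, reconstruction
from skimage.segmentation import watershed

from .extractor import DetectedObject

BACKGROUND_4CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=int)
FOREGROUND_8CONN = np.ones((3, 3), dtype=int)


@dataclass(frozen=True)
class TriageRule:
    wh_min: int = 25
    wh_max: int = 65
    ih_max: int = 3

    def __post_init__(self):
        if not self.wh_min < self.wh_max:
            raise ValueError("wh_min must be < wh_max")
        if self.ih_max < 0:
            raise ValueError("ih_max must be >= 0")


@dataclass(frozen=True)
class SegmenterConfig:
    min_seed_area: int = 150
    seed_method: str = "distance-maxima"    # or "distance-threshold"
    # distance-maxima: markers = regional-maximum plateaus of the EDT
    # after h-reconstruction at depth h_rel * max; calibrated so blob
    # pairs whose waist is >~23% shallower than their cores split, while
    # centromeric pinches (~18%) do not.
    h_rel: float = 0.22
    # distance-threshold: markers = components of EDT > threshold_rel * max
    threshold_rel: float = 0.5

    def __post_init__(self):
        if self.min_seed_area < 1:
            raise ValueError("min_seed_area must be >= 1")
        if self.seed_method not in ("distance-maxima", "distance-threshold"):
            raise ValueError(f"unknown seed_method {self.seed_method!r}")


def measure_width(mask: np.ndarray) -> int:
    """WH: short side of the minimum-area enclosing rectangle, in px.

    Rotating calipers on the convex hull of the pixel *corners* (so a
    1-px-thick line has width 1); the minimum-area rectangle shares an
    edge direction with some hull edge.  Rounded to the nearest integer.
    """
    mask = np.asarray(mask, dtype=bool)
    coords = np.argwhere(mask).astype(np.float64)
    if coords.size == 0:
        raise ValueError("empty mask has no width")
    corners = np.concatenate([coords + off for off in
                              ([0, 0], [0, 1], [1, 0], [1, 1])])
    try:
        hull = corners[ConvexHull(corners).vertices]
    except QhullError:  # pragma: no cover - corners are never collinear
        hull = corners
    edges = np.diff(np.vstack([hull, hull[:1]]), axis=0)
    angles = np.unique(np.mod(np.arctan2(edges[:, 0], edges[:, 1]), np.pi / 2))
    best_area, best_short = np.inf, np.inf
    for a in angles:
        u = np.array([np.sin(a), np.cos(a)])      # edge direction
        v = np.array([np.cos(a), -np.sin(a)])     # its normal
        pu, pv = hull @ u, hull @ v
        ext = np.array([pu.max() - pu.min(), pv.max() - pv.min()])
        area = ext[0] * ext[1]
        if area < best_area:
            best_area, best_short = area, ext.min()
    return int(round(best_short))


def count_holes(mask: np.ndarray) -> int:
    """IH: number of background regions fully enclosed by the foreground.

    Background is 4-connected (foreground 8-connected); after 1-px padding
    the outside is a single background component, so holes are the
    remaining background components.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask has no holes")
    padded = np.pad(mask, 1)
    _, n_bg = ndimage.label(~padded, structure=BACKGROUND_4CONN)
    return int(n_bg - 1)


def triage(WH: int, IH: int, rule: TriageRule | None = None) -> str:
    """Total classification of the (WH, IH) plane into exactly one of
    impurity / mass / individual."""
    rule = rule or TriageRule()
    if WH < 1 or IH < 0:
        raise ValueError("require WH >= 1 and IH >= 0")
    if WH < rule.wh_min or IH > rule.ih_max:
        return "impurity"
    if WH > rule.wh_max:
        return "mass"
    return "individual"


def _markers(dist: np.ndarray, mask: np.ndarray,
             config: SegmenterConfig) -> np.ndarray:
    dmax = float(dist.max())
    if dmax <= 0:
        return np.zeros_like(mask, dtype=np.int32)
    if config.seed_method == "distance-maxima":
        h = max(config.h_rel * dmax, 1e-6)
        rec = reconstruction(dist - h, dist, method="dilation")
        seeds = local_maxima(rec, connectivity=2)
    else:
        seeds = dist > config.threshold_rel * dmax
    seeds &= mask
    labels, n = ndimage.label(seeds, structure=FOREGROUND_8CONN)
    if n == 0:
        return labels.astype(np.int32)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    keep = np.flatnonzero(areas >= config.min_seed_area) + 1
    out = np.zeros_like(labels, dtype=np.int32)
    for new, lab in enumerate(keep, start=1):
        out[labels == lab] = new
    return out


def segment_mass(mass: DetectedObject,
                 config: SegmenterConfig | None = None) -> list[DetectedObject]:
    """Split an adhesive chromosome mass by seed-filtered watershed.

    Markers with area below ``min_seed_area`` are dropped before flooding;
    if at most one marker survives the mass is returned unsplit.  The
    output segments are pairwise disjoint and their union is exactly the
    input mask (every mask pixel is flooded from some marker), so area is
    conserved.
    """
    config = config or SegmenterConfig()
    mask = np.asarray(mass.mask_crop, dtype=bool)
    dist = ndimage.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1]
    markers = _markers(dist, mask, config)
    n_seeds = markers.max()
    if n_seeds <= 1:
        return [mass]
    ws = watershed(-dist, markers, mask=mask)
    segments: list[DetectedObject] = []
    for lab in range(1, n_seeds + 1):
        seg = ws == lab
        if not seg.any():
            continue
        rr, cc = np.nonzero(seg)
        r0, r1 = int(rr.min()), int(rr.max()) + 1
        c0, c1 = int(cc.min()), int(cc.max()) + 1
        pr0, pc0 = mass.bbox[0], mass.bbox[1]
        crop = seg[r0:r1, c0:c1]
        img = None
        if mass.image_crop is not None:
            img = np.array(mass.image_crop[r0:r1, c0:c1])
            bg = 230 if img.dtype == np.uint8 else img.max()
            img[~crop] = bg
        segments.append(DetectedObject(
            mask_crop=crop,
            bbox=(pr0 + r0, pc0 + c0, pr0 + r1, pc0 + c1),
            centroid=(float(rr.mean()) + pr0, float(cc.mean()) + pc0),
            image_crop=img,
            parent_mass_id=mass.object_id,
        ))
    if len(segments) <= 1:
        return [mass]
    return segments


def triage_objects(objects: list[DetectedObject],
                   rule: TriageRule | None = None,
                   config: SegmenterConfig | None = None,
                   max_depth: int = 2) -> list[DetectedObject]:
    """Measure WH/IH, categorise, split masses, and re-triage the split
    segments (recursion capped so pathological masses terminate)."""
    rule = rule or TriageRule()
    config = config or SegmenterConfig()
    out: list[DetectedObject] = []
    for ob in objects:
        ob.WH = measure_width(ob.mask_crop)
        ob.IH = count_holes(ob.mask_crop)
        ob.category = triage(ob.WH, ob.IH, rule)
        if ob.category == "mass" and max_depth > 0:
            parts = segment_mass(ob, config)
            if len(parts) > 1:
                out.extend(triage_objects(parts, rule, config, max_depth - 1))
                continue
        out.append(ob)
    return out
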