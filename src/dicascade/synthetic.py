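"""Seeded synthetic Giemsa-spread generator.

Emulates the imagery the identification pipeline consumes: 10x grayscale
field images (metaphase spreads as pore-like clusters of thin strokes,
nuclei as blocky blobs, debris as specks) and 100x RGB metaphase images
(dark elongated chromosome bodies, 25-65 px wide, on a light background).
Dicentric bodies enclose exactly one internal background hole between
their two centromeric constrictions, tricentrics two, monocentrics none,
so the downstream width/hole triage and the CNN cascade can be exercised
with exact per-object ground truth and no real slide data.

All randomness flows through one ``numpy.random.Generator`` per call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from PIL import Image

# ---------------------------------------------------------------------------
# Rendering constants (Giemsa-like contrast; all config-exposed via kwargs)
# ---------------------------------------------------------------------------

BACKGROUND_LEVEL = 230          # light background, 8-bit
BODY_LEVEL = 60                 # dark chromatin
CHROMOSOME_WIDTH_RANGE = (25.0, 65.0)   # px, full body width at 100x
MIN_HOLE_AREA = 30.0            # px^2, keeps hole counting robust
CENTROMERE_PINCH = 0.82         # half-width factor at a centromere
END_TAPER = 0.45                # half-width factor at the body tips
HOLE_HALFWIDTH_FACTOR = 0.5     # hole half-width / local body half-width

KIND_CENTROMERES = {"monocentric": 1, "dicentric": 2, "tricentric": 3}


class PlacementError(RuntimeError):
    """Canvas too small / too crowded for the requested object count."""


@dataclass
class ObjectSpec:
    """Geometric description of one renderable object.

    ``backbone`` is a polyline in local (row, col) coordinates,
    ``width_profile`` the per-vertex half-width in px, and
    ``centromere_positions`` arc-length fractions in [0, 1].
    ``pose`` is (translation_row, translation_col, rotation_rad).
    """

    kind: str
    backbone: np.ndarray
    width_profile: np.ndarray
    centromere_positions: list[float] = field(default_factory=list)
    pose: tuple[float, float, float] = (0.0, 0.0, 0.0)
    hole_windows: list[tuple[float, float]] = field(default_factory=list)
    body_level: float = BODY_LEVEL

    @property
    def n_centromeres(self) -> int:
        return len(self.centromere_positions)


@dataclass
class RenderedObject:
    spec: ObjectSpec
    mask: np.ndarray            # bool crop
    origin: tuple[int, int]     # (row, col) of mask[0, 0] in the canvas
    label: str                  # DIC / non-DIC / impurity / mass-member

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        r0, c0 = self.origin
        return (r0, c0, r0 + self.mask.shape[0], c0 + self.mask.shape[1])

    @property
    def centroid(self) -> tuple[float, float]:
        rr, cc = np.nonzero(self.mask)
        return (float(rr.mean()) + self.origin[0], float(cc.mean()) + self.origin[1])


@dataclass
class GroundTruth:
    objects: list[RenderedObject] = field(default_factory=list)
    metaphase_centroids: list[tuple[float, float]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ob in self.objects:
            out[ob.spec.kind] = out.get(ob.spec.kind, 0) + 1
        return out


# ---------------------------------------------------------------------------
# Chromosome geometry
# ---------------------------------------------------------------------------

def make_chromosome(
    kind: str,
    length_px: float = 150.0,
    width_px: float = 40.0,
    curvature: float = 0.0,
    seed: int | np.random.Generator = 0,
    width_range: tuple[float, float] = CHROMOSOME_WIDTH_RANGE,
    n_vertices: int = 25,
) -> ObjectSpec:
    """Build one chromosome body as a gently curved thick polyline.

    ``curvature`` is the total turn of the backbone in radians; it is kept
    small by the callers so the short side of the minimum enclosing
    rectangle tracks ``width_px`` (the triage WH feature).  Dicentrics get
    two centromeric constrictions with an enclosed gap between them,
    tricentrics three constrictions and two gaps.
    """
    if kind not in KIND_CENTROMERES:
        raise ValueError(f"unknown chromosome kind: {kind!r}")
    if not (width_range[0] <= width_px <= width_range[1]):
        raise ValueError(
            f"width {width_px} outside configured range {width_range}")
    if length_px <= 0:
        raise ValueError("length_px must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    n = KIND_CENTROMERES[kind]
    if n == 1:
        cents = [float(rng.uniform(0.35, 0.65))]
    elif n == 2:
        cents = [float(rng.uniform(0.20, 0.30)), float(rng.uniform(0.70, 0.80))]
    else:
        cents = [float(rng.uniform(0.12, 0.20)), float(rng.uniform(0.44, 0.56)),
                 float(rng.uniform(0.80, 0.88))]

    # Backbone: heading turns linearly by `curvature` over the arc, plus a
    # little smooth jitter; sampled at n_vertices points.
    t = np.linspace(0.0, 1.0, n_vertices)
    # cap total turn so the backbone sagitta (~L*turn/8) stays ~<1.2 px and
    # the min-area-rectangle short side tracks the requested width
    turn = float(np.clip(curvature, -9.0 / length_px, 9.0 / length_px))
    theta = turn * (t - 0.5)
    theta = theta + rng.normal(0.0, 0.003, n_vertices).cumsum()
    step = length_px / (n_vertices - 1)
    dr = np.sin(theta) * step
    dc = np.cos(theta) * step
    backbone = np.stack([np.concatenate([[0.0], dr]).cumsum()[1:],
                         np.concatenate([[0.0], dc]).cumsum()[1:]], axis=1)
    backbone -= backbone.mean(axis=0)

    halfw = np.full(n_vertices, width_px / 2.0)
    # taper at both tips
    taper = np.minimum(t, 1.0 - t) / 0.10
    halfw *= END_TAPER + (1.0 - END_TAPER) * np.clip(taper, 0.0, 1.0)
    # pinch at each centromere
    for c in cents:
        halfw *= 1.0 - (1.0 - CENTROMERE_PINCH) * np.exp(-((t - c) / 0.05) ** 2)

    # enclosed gap between consecutive centromeres, kept clear of the pinches
    holes: list[tuple[float, float]] = []
    for a, b in zip(cents[:-1], cents[1:]):
        margin = 0.06
        lo, hi = a + margin, b - margin
        hole_hw = HOLE_HALFWIDTH_FACTOR * (width_px / 2.0)
        min_len = max(8.0, MIN_HOLE_AREA / (2.0 * hole_hw)) / length_px
        if hi - lo < min_len:
            mid = 0.5 * (lo + hi)
            lo, hi = mid - min_len / 2, mid + min_len / 2
        holes.append((lo, hi))

    return ObjectSpec(kind=kind, backbone=backbone, width_profile=halfw,
                      centromere_positions=cents, hole_windows=holes)


def make_entangled_chromosome(
    length_px: float = 140.0,
    width_px: float = 32.0,
    seed: int | np.random.Generator = 0,
) -> ObjectSpec:
    """Monocentric chromosome with its long arms entangled near one tip.

    The backbone loops back over itself, enclosing a background hole that
    is *not* flanked by two centromeres — the classic confuser that a
    width/hole rule (and an under-trained first-stage CNN) mistakes for a
    dicentric.  Ground-truth label stays non-DIC.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = 40
    t = np.linspace(0.0, 1.0, n)
    # straight shaft, a full loop of radius r, then a short tail, so the
    # enclosed hole can sit anywhere from mid-body to the tip
    r_loop = width_px * float(rng.uniform(0.60, 1.00))
    shaft = float(rng.uniform(0.35, 0.60)) * length_px
    tail = float(rng.uniform(0.0, 0.30)) * length_px
    loop_arc = 2.0 * np.pi * 1.08          # slightly past closure -> overlap
    arc = shaft + loop_arc * r_loop + tail
    s = t * arc
    theta = np.where(s < shaft, 0.0,
                     np.minimum(s - shaft, loop_arc * r_loop) / r_loop)
    theta = theta + rng.normal(0.0, 0.01, n).cumsum()
    ds = np.gradient(s)
    backbone = np.stack([(np.sin(theta) * ds).cumsum(),
                         (np.cos(theta) * ds).cumsum()], axis=1)
    backbone -= backbone.mean(axis=0)
    halfw = np.full(n, width_px / 2.0)
    taper = np.minimum(t, 1.0 - t) / 0.08
    halfw *= END_TAPER + (1.0 - END_TAPER) * np.clip(taper, 0.0, 1.0)
    c = float(rng.uniform(0.20, 0.35))
    halfw *= 1.0 - (1.0 - CENTROMERE_PINCH) * np.exp(-((t - c) / 0.05) ** 2)
    return ObjectSpec(kind="monocentric", backbone=backbone,
                      width_profile=halfw, centromere_positions=[c])


def make_nucleus(radius_px: float, eccentricity: float,
                 seed: int | np.random.Generator = 0) -> ObjectSpec:
    """Nucleus as a filled ellipse, described by a short fat backbone."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    half_len = radius_px * eccentricity
    backbone = np.array([[0.0, -half_len], [0.0, 0.0], [0.0, half_len]])
    halfw = np.full(3, radius_px)
    return ObjectSpec(kind="nucleus", backbone=backbone, width_profile=halfw,
                      body_level=BODY_LEVEL + 40 + rng.uniform(-10, 10))


def make_debris(radius_px: float,
                seed: int | np.random.Generator = 0) -> ObjectSpec:
    backbone = np.array([[0.0, -0.5], [0.0, 0.5]])
    return ObjectSpec(kind="debris", backbone=backbone,
                      width_profile=np.full(2, radius_px))


# ---------------------------------------------------------------------------
# Rasterisation
# ---------------------------------------------------------------------------

def _polyline_distance(points: np.ndarray, poly: np.ndarray):
    """Distance from each point to a polyline, plus arc-length fraction of
    the nearest polyline point.  ``points`` (K,2), ``poly`` (M,2).

    Segment-by-segment running minimum in float32: small temporaries,
    cache friendly, ~5x faster than the broadcast (K,S) formulation.
    """
    pts = np.asarray(points, dtype=np.float32)
    poly = np.asarray(poly, dtype=np.float32)
    p0 = poly[:-1]
    d = poly[1:] - p0
    seglen2 = np.maximum((d ** 2).sum(axis=1), 1e-12)
    seglen = np.sqrt(seglen2)
    cum = np.concatenate([[0.0], seglen.cumsum()]).astype(np.float32)
    total = max(float(cum[-1]), 1e-12)

    k = pts.shape[0]
    best_d2 = np.full(k, np.inf, dtype=np.float32)
    best_arc = np.zeros(k, dtype=np.float32)
    pr, pc = pts[:, 0], pts[:, 1]
    for i in range(p0.shape[0]):
        dr = pr - p0[i, 0]
        dc = pc - p0[i, 1]
        t = (dr * d[i, 0] + dc * d[i, 1]) / seglen2[i]
        np.clip(t, 0.0, 1.0, out=t)
        er = dr - t * d[i, 0]
        ec = dc - t * d[i, 1]
        d2 = er * er + ec * ec
        closer = d2 < best_d2
        best_d2[closer] = d2[closer]
        best_arc[closer] = cum[i] + t[closer] * seglen[i]
    return np.sqrt(best_d2), best_arc / total


def render_object(spec: ObjectSpec, pad: int = 4):
    """Rasterise one ObjectSpec in its posed frame.

    Returns ``(mask, origin)`` where ``mask`` is a tight boolean crop and
    ``origin`` its top-left (row, col) in canvas coordinates.
    """
    tr, tc, rot = spec.pose
    c, s = np.cos(rot), np.sin(rot)
    R = np.array([[c, -s], [s, c]])
    poly = spec.backbone @ R.T + np.array([tr, tc])

    hw_max = float(spec.width_profile.max())
    r0 = int(np.floor(poly[:, 0].min() - hw_max)) - pad
    c0 = int(np.floor(poly[:, 1].min() - hw_max)) - pad
    r1 = int(np.ceil(poly[:, 0].max() + hw_max)) + pad
    c1 = int(np.ceil(poly[:, 1].max() + hw_max)) + pad
    rows = np.arange(r0, r1 + 1)
    cols = np.arange(c0, c1 + 1)
    grid = np.stack(np.meshgrid(rows, cols, indexing="ij"), axis=-1).reshape(-1, 2)

    dist, frac = _polyline_distance(grid.astype(np.float64), poly)
    t_axis = np.linspace(0.0, 1.0, len(spec.width_profile))
    hw = np.interp(frac, t_axis, spec.width_profile)
    # -0.5: pixel centres within the half-width band, so the rasterised
    # body thickness matches 2*hw once pixel extent is accounted for
    body = dist <= hw - 0.5
    hole = np.zeros_like(body)
    for lo, hi in spec.hole_windows:
        hole |= (dist <= HOLE_HALFWIDTH_FACTOR * hw) & (frac > lo) & (frac < hi)
    mask = (body & ~hole).reshape(len(rows), len(cols))
    return mask, (r0, c0)


def _tight_crop(mask: np.ndarray, origin: tuple[int, int]):
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        return mask, origin
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    return mask[r0:r1, c0:c1], (origin[0] + r0, origin[1] + c0)


# ---------------------------------------------------------------------------
# Scene composition
# ---------------------------------------------------------------------------

def plan_spread(n_chromosomes: int, dic_fraction: float,
                rng: np.random.Generator,
                tricentric_fraction: float = 0.0) -> list[str]:
    """Draw the chromosome kinds of one spread (Bernoulli per body)."""
    kinds = []
    for _ in range(n_chromosomes):
        u = rng.random()
        if u < dic_fraction:
            kinds.append("dicentric")
        elif u < dic_fraction + tricentric_fraction:
            kinds.append("tricentric")
        else:
            kinds.append("monocentric")
    return kinds


def _paint(canvas: np.ndarray, rnd: RenderedObject, rng: np.random.Generator,
           level: Optional[float] = None, texture_sigma: float = 8.0) -> None:
    r0, c0, r1, c1 = rnd.bbox
    H, W = canvas.shape
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r1, H), min(c1, W)
    if rr1 <= rr0 or cc1 <= cc0:
        return
    sub = rnd.mask[rr0 - r0:rr1 - r0, cc0 - c0:cc1 - c0]
    lvl = rnd.spec.body_level if level is None else level
    vals = lvl + rng.normal(0.0, texture_sigma, sub.shape)
    region = canvas[rr0:rr1, cc0:cc1]
    region[sub] = np.minimum(region[sub], vals[sub])   # dark wins


def _place_disjoint(occupancy: np.ndarray, spec: ObjectSpec,
                    rng: np.random.Generator, margin: int = 3,
                    max_rotations: int = 6, tries_per_rotation: int = 150
                    ) -> RenderedObject:
    """Random pose rejection-sampled so the mask (dilated by `margin`)
    misses everything already placed.  The raster is grid-aligned, so an
    integer translation reuses the same mask; only a new rotation forces
    a re-render."""
    from scipy import ndimage

    H, W = occupancy.shape
    for _ in range(max_rotations):
        rot = rng.uniform(0.0, np.pi)
        spec.pose = (0.0, 0.0, rot)
        mask, origin = _tight_crop(*render_object(spec))
        h, w = mask.shape
        if h + 2 * margin >= H or w + 2 * margin >= W:
            continue
        grown = ndimage.binary_dilation(np.pad(mask, margin), iterations=margin)
        for _ in range(tries_per_rotation):
            r = int(rng.integers(margin, H - h - margin))
            c = int(rng.integers(margin, W - w - margin))
            window = occupancy[r - margin:r - margin + grown.shape[0],
                               c - margin:c - margin + grown.shape[1]]
            if window.shape == grown.shape and not (window & grown).any():
                occupancy[r:r + h, c:c + w] |= mask
                spec.pose = (spec.pose[0] + r - origin[0],
                             spec.pose[1] + c - origin[1], rot)
                return RenderedObject(spec, mask, (r, c), label="")
    raise PlacementError("could not place object without overlap")


def _touch_pose(spec: ObjectSpec, target_spec: ObjectSpec, rot: float,
                depth: float, anchor_frac: float,
                rng: np.random.Generator) -> None:
    """Pose ``spec`` (rotation ``rot``) so one of its tapered tips sits
    ``depth`` px inside the target's boundary at ``anchor_frac`` along the
    target backbone — shallow end-to-side contact, the common adhesive
    configuration (telomere touching a neighbour's side)."""
    tr, tc, trot = target_spec.pose
    c, s = np.cos(trot), np.sin(trot)
    tpoly = target_spec.backbone @ np.array([[c, -s], [s, c]]).T + np.array([tr, tc])
    i = int(np.clip(anchor_frac * (len(tpoly) - 1), 1, len(tpoly) - 2))
    tangent = tpoly[i + 1] - tpoly[i - 1]
    tangent /= max(np.linalg.norm(tangent), 1e-9)
    normal = np.array([tangent[1], -tangent[0]])
    hw_local = float(target_spec.width_profile[i])

    cb, sb = np.cos(rot), np.sin(rot)
    poly_b = spec.backbone @ np.array([[cb, -sb], [sb, cb]]).T
    centre = poly_b.mean(axis=0)
    best = None
    for tip in (poly_b[0], poly_b[-1]):
        d = centre - tip
        d /= max(np.linalg.norm(d), 1e-9)
        for sign in (1.0, -1.0):
            score = float(d @ (normal * sign))
            if best is None or score > best[0]:
                best = (score, tip, sign)
    _, tip, sign = best
    tip_target = tpoly[i] + sign * normal * (hw_local - depth)
    shift = tip_target - tip
    spec.pose = (float(shift[0]), float(shift[1]), rot)


def _place_touching(target: RenderedObject, spec: ObjectSpec,
                    rng: np.random.Generator, canvas_shape,
                    max_tries: int = 60) -> RenderedObject:
    """Attach `spec` to an already placed body by shallow tip contact."""
    H, W = canvas_shape
    for _ in range(max_tries):
        _touch_pose(spec, target.spec, rng.uniform(0.0, np.pi),
                    rng.uniform(2.0, 5.0), rng.uniform(0.3, 0.7), rng)
        mask, origin = _tight_crop(*render_object(spec))
        r0, c0 = origin
        if r0 < 0 or c0 < 0 or r0 + mask.shape[0] >= H or c0 + mask.shape[1] >= W:
            continue
        # require actual contact so the pair really is one mass
        tm = np.zeros(canvas_shape, dtype=bool)
        t0, t1, t2, t3 = target.bbox
        tm[t0:t2, t1:t3] = target.mask
        from scipy import ndimage as _ndi
        sub = tm[r0:r0 + mask.shape[0], c0:c0 + mask.shape[1]]
        if (_ndi.binary_dilation(mask) & sub).any():
            return RenderedObject(spec, mask, origin, label="")
    raise PlacementError("could not attach overlapping chromosome")


def render_metaphase(
    n_chromosomes: int = 46,
    dic_fraction: float = 0.0,
    overlap_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
    canvas_shape: tuple[int, int] = (1200, 1200),
    noise_sigma: float = 3.0,
    kinds: Optional[Sequence[str]] = None,
    n_nuclei: int = 0,
    n_debris: int = 0,
):
    """Render one 100x metaphase image (8-bit RGB) plus ground truth.

    ``overlap_fraction`` of the chromosomes are attached end-to-side to an
    already placed body, forming adhesive masses; ground truth keeps the
    individual masks even inside masses.  Optional nuclei (large compact
    blobs) and debris specks emulate the contaminants that surround real
    spreads; both carry the impurity label.
    """
    if n_chromosomes < 1:
        raise ValueError("n_chromosomes must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if kinds is None:
        kinds = plan_spread(n_chromosomes, dic_fraction, rng)
    if len(kinds) != n_chromosomes:
        raise ValueError("kinds length must match n_chromosomes")

    n_overlap = int(round(overlap_fraction * n_chromosomes))
    canvas = np.full(canvas_shape, float(BACKGROUND_LEVEL))
    occupancy = np.zeros(canvas_shape, dtype=bool)
    truth = GroundTruth()

    def _new_spec(kind):
        length = float(rng.uniform(90, 200))
        width = float(rng.uniform(26, 60))
        curv = float(rng.uniform(-0.12, 0.12))
        sp = make_chromosome(kind, length, width, curv, rng)
        sp.body_level = BODY_LEVEL + float(rng.uniform(-15, 15))
        return sp

    # nuclei first: they are by far the largest bodies, so they claim
    # space before the canvas fills with chromosomes
    nuclei: list[RenderedObject] = []
    for _ in range(n_nuclei):
        spec = make_nucleus(float(rng.uniform(55, 95)),
                            float(rng.uniform(1.0, 1.4)), rng)
        rnd = _place_disjoint(occupancy, spec, rng)
        rnd.label = "impurity"
        nuclei.append(rnd)

    placed: list[RenderedObject] = []
    for kind in kinds[:n_chromosomes - n_overlap]:
        rnd = _place_disjoint(occupancy, _new_spec(kind), rng)
        rnd.label = "DIC" if kind == "dicentric" else "non-DIC"
        placed.append(rnd)
        truth.objects.append(rnd)
    for kind in kinds[n_chromosomes - n_overlap:]:
        if not placed:
            raise PlacementError("overlap requested with no placed bodies")
        target = placed[int(rng.integers(len(placed)))]
        rnd = _place_touching(target, _new_spec(kind), rng, canvas_shape)
        rnd.label = "mass-member"
        if target.label != "mass-member":
            target.label = "mass-member"
        truth.objects.append(rnd)

    truth.objects.extend(nuclei)
    for _ in range(n_debris):
        spec = make_debris(float(rng.uniform(2.0, 5.0)), rng)
        spec.body_level = BODY_LEVEL + float(rng.uniform(20, 60))
        rnd = _place_disjoint(occupancy, spec, rng)
        rnd.label = "impurity"
        truth.objects.append(rnd)

    for rnd in truth.objects:
        _paint(canvas, rnd, rng)
    canvas += rng.normal(0.0, noise_sigma, canvas_shape)
    gray = np.clip(canvas, 0, 255)
    # slight Giemsa-violet tint
    rgb = np.stack([gray * 1.00, gray * 0.94, gray * 1.03], axis=-1)
    image = np.clip(rgb, 0, 255).astype(np.uint8)
    return image, truth


def render_field_10x(
    n_metaphases: int = 3,
    n_nuclei: int = 5,
    n_debris: int = 10,
    seed: int | np.random.Generator = 0,
    canvas_shape: tuple[int, int] = (768, 768),
    noise_sigma: float = 3.0,
):
    """Render one 10x grayscale field: metaphases as pore-like clusters of
    thin strokes, nuclei as blocky ellipses, debris as specks."""
    if min(n_metaphases, n_nuclei, n_debris) < 0:
        raise ValueError("counts must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    canvas = np.full(canvas_shape, float(BACKGROUND_LEVEL + 5))
    occupancy = np.zeros(canvas_shape, dtype=bool)
    truth = GroundTruth()

    from scipy import ndimage

    def _reserve(center, radius):
        rr = int(center[0]); cc = int(center[1]); rad = int(radius) + 6
        r0, r1 = max(rr - rad, 0), min(rr + rad, canvas_shape[0])
        c0, c1 = max(cc - rad, 0), min(cc + rad, canvas_shape[1])
        occupancy[r0:r1, c0:c1] = True

    def _free_center(radius, max_tries=300):
        rad = int(radius) + 6
        for _ in range(max_tries):
            r = int(rng.integers(rad, canvas_shape[0] - rad))
            c = int(rng.integers(rad, canvas_shape[1] - rad))
            if not occupancy[max(r - rad, 0):r + rad, max(c - rad, 0):c + rad].any():
                return (r, c)
        raise PlacementError("field canvas too crowded")

    # metaphase spreads: ~46 thin strokes packed in a ~35 px radius, dense
    # enough to read as one pore-like cluster
    for _ in range(n_metaphases):
        radius = rng.uniform(28, 40)
        center = _free_center(radius * 1.6)
        _reserve(center, radius * 1.4)
        n_strokes = int(rng.integers(42, 50))
        for _ in range(n_strokes):
            ang = rng.uniform(0, np.pi)
            rad_pos = radius * np.sqrt(rng.random())
            phi = rng.uniform(0, 2 * np.pi)
            pos = np.array(center) + rad_pos * np.array([np.sin(phi), np.cos(phi)])
            length = rng.uniform(7, 13)
            d = np.array([np.sin(ang), np.cos(ang)]) * length / 2
            spec = ObjectSpec(kind="stroke",
                              backbone=np.array([pos - d, pos + d]),
                              width_profile=np.full(2, rng.uniform(0.9, 1.4)),
                              body_level=BODY_LEVEL + rng.uniform(-10, 20))
            mask, origin = _tight_crop(*render_object(spec, pad=2))
            _paint(canvas, RenderedObject(spec, mask, origin, "metaphase-stroke"),
                   rng, texture_sigma=5.0)
        truth.metaphase_centroids.append((float(center[0]), float(center[1])))

    for _ in range(n_nuclei):
        radius = rng.uniform(15, 28)
        center = _free_center(radius * 1.4)
        _reserve(center, radius * 1.4)
        spec = make_nucleus(radius, rng.uniform(1.0, 1.5), rng)
        spec.pose = (float(center[0]), float(center[1]), rng.uniform(0, np.pi))
        mask, origin = _tight_crop(*render_object(spec))
        rnd = RenderedObject(spec, mask, origin, "impurity")
        truth.objects.append(rnd)
        _paint(canvas, rnd, rng, texture_sigma=6.0)

    for _ in range(n_debris):
        radius = rng.uniform(0.8, 2.0)
        center = (int(rng.integers(8, canvas_shape[0] - 8)),
                  int(rng.integers(8, canvas_shape[1] - 8)))
        spec = make_debris(radius, rng)
        spec.pose = (float(center[0]), float(center[1]), 0.0)
        mask, origin = _tight_crop(*render_object(spec, pad=2))
        rnd = RenderedObject(spec, mask, origin, "impurity")
        truth.objects.append(rnd)
        _paint(canvas, rnd, rng, level=BODY_LEVEL + 30, texture_sigma=5.0)

    canvas += rng.normal(0.0, noise_sigma, canvas_shape)
    return np.clip(canvas, 0, 255).astype(np.uint8), truth


def make_adhesive_pair(angle_rad: float = np.pi / 2,
                       seed: int | np.random.Generator = 0):
    """Two chromosomes touching end-to-side at a given crossing angle.

    Chromosome B's tapered tip penetrates a few px into chromosome A's
    side, the common adhesive configuration (telomere contact).  Returns
    ``(mass_mask, (mask_a, mask_b))`` on a shared tight canvas; the
    component masks let tests check how a split should look.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = make_chromosome("monocentric", float(rng.uniform(130, 180)),
                        float(rng.uniform(30, 44)), 0.0, rng)
    b = make_chromosome("monocentric", float(rng.uniform(130, 180)),
                        float(rng.uniform(30, 44)), 0.0, rng)
    a.pose = (300.0, 300.0, 0.0)
    mask_a, origin_a = _tight_crop(*render_object(a))
    for _ in range(20):
        _touch_pose(b, a, angle_rad, float(rng.uniform(1.0, 2.5)),
                    float(rng.uniform(0.3, 0.7)), rng)
        mask_b, origin_b = _tight_crop(*render_object(b))
        from scipy import ndimage as _ndi
        lo_r = min(origin_a[0], origin_b[0]); lo_c = min(origin_a[1], origin_b[1])
        hi_r = max(origin_a[0] + mask_a.shape[0], origin_b[0] + mask_b.shape[0])
        hi_c = max(origin_a[1] + mask_a.shape[1], origin_b[1] + mask_b.shape[1])
        fa_try = np.zeros((hi_r - lo_r, hi_c - lo_c), dtype=bool)
        fb_try = np.zeros_like(fa_try)
        fa_try[origin_a[0] - lo_r:origin_a[0] - lo_r + mask_a.shape[0],
               origin_a[1] - lo_c:origin_a[1] - lo_c + mask_a.shape[1]] = mask_a
        fb_try[origin_b[0] - lo_r:origin_b[0] - lo_r + mask_b.shape[0],
               origin_b[1] - lo_c:origin_b[1] - lo_c + mask_b.shape[1]] = mask_b
        if (_ndi.binary_dilation(fa_try) & fb_try).any():
            return fa_try | fb_try, (fa_try, fb_try)
    raise PlacementError("could not form a touching pair")


# ---------------------------------------------------------------------------
# Chromosome tile corpus (CNN food)
# ---------------------------------------------------------------------------

def plan_tile_labels(n_tiles: int, non_dic_to_dic_ratio: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Bernoulli DIC/non-DIC label stream at the requested population ratio
    (1 = DIC).  Non-DIC : DIC expectation is ``ratio`` : 1."""
    p_dic = 1.0 / (non_dic_to_dic_ratio + 1.0)
    return (rng.random(n_tiles) < p_dic).astype(np.int64)


def render_chromosome_tile(kind: str, rng: np.random.Generator,
                           entangled: bool = False,
                           noise_sigma: float = 3.0) -> np.ndarray:
    """Render one isolated chromosome crop (uint8 RGB, tight bbox + pad)."""
    if entangled:
        spec = make_entangled_chromosome(float(rng.uniform(110, 170)),
                                         float(rng.uniform(26, 40)), rng)
    else:
        spec = make_chromosome(kind, float(rng.uniform(90, 200)),
                               float(rng.uniform(26, 60)),
                               float(rng.uniform(-0.12, 0.12)), rng)
    spec.pose = (0.0, 0.0, float(rng.uniform(0, np.pi)))
    spec.body_level = BODY_LEVEL + float(rng.uniform(-15, 15))
    mask, _ = _tight_crop(*render_object(spec))
    h, w = mask.shape
    canvas = np.full((h, w), float(BACKGROUND_LEVEL))
    vals = spec.body_level + rng.normal(0.0, 8.0, (h, w))
    canvas[mask] = vals[mask]
    canvas += rng.normal(0.0, noise_sigma, (h, w))
    gray = np.clip(canvas, 0, 255)
    rgb = np.stack([gray, gray * 0.94, gray * 1.03], axis=-1)
    return np.clip(rgb, 0, 255).astype(np.uint8)


def make_tile_dataset(
    n_tiles: int,
    non_dic_to_dic_ratio: float = 45.0,
    seed: int | np.random.Generator = 0,
    entangled_fraction: float = 0.3,
    tile_size: int = 151,
):
    """Seeded in-memory labeled tile corpus for CNN training.

    Returns ``(tiles, labels)`` with ``tiles`` uint8 of shape
    (n, tile_size, tile_size, 3) and ``labels`` 1 for DIC, 0 for non-DIC.
    ``entangled_fraction`` of the non-DIC tiles are long-arm-entangled
    confusers so the classification problem is not trivially separable.
    """
    from .cnn import normalize_tile

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    labels = plan_tile_labels(n_tiles, non_dic_to_dic_ratio, rng)
    tiles = np.empty((n_tiles, tile_size, tile_size, 3), dtype=np.uint8)
    for i, lab in enumerate(labels):
        if lab == 1:
            crop = render_chromosome_tile("dicentric", rng)
        elif rng.random() < entangled_fraction:
            crop = render_chromosome_tile("monocentric", rng, entangled=True)
        else:
            crop = render_chromosome_tile("monocentric", rng)
        tiles[i] = (normalize_tile(crop, size=tile_size) * 255).astype(np.uint8)
    return tiles, labels


# ---------------------------------------------------------------------------
# On-disk corpus
# ---------------------------------------------------------------------------

@dataclass
class CorpusConfig:
    n_fields: int = 2
    n_metaphases_per_field: int = 3
    n_nuclei_per_field: int = 5
    n_debris_per_field: int = 8
    n_spreads: int = 2
    n_chromosomes: int = 46
    dic_fraction: float = 0.05
    overlap_fraction: float = 0.0
    n_tiles: int = 0
    non_dic_to_dic_ratio: float = 45.0
    canvas_10x: tuple[int, int] = (768, 768)
    canvas_100x: tuple[int, int] = (1200, 1200)


def _bbox_of(ob: RenderedObject) -> list[int]:
    return [int(v) for v in ob.bbox]


def generate_corpus(config: CorpusConfig, out_dir: str | Path, seed: int):
    """Write a PNG corpus + JSON manifest; identical seed, identical manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    manifest: dict = {"seed": int(seed), "images": []}

    for i in range(config.n_fields):
        img, truth = render_field_10x(
            config.n_metaphases_per_field, config.n_nuclei_per_field,
            config.n_debris_per_field, rng, canvas_shape=config.canvas_10x)
        name = f"field_{i:03d}.png"
        Image.fromarray(img).save(out / name)
        manifest["images"].append({
            "path": name, "magnification": "10x",
            "metaphase_centroids": [[round(r, 2), round(c, 2)]
                                    for r, c in truth.metaphase_centroids],
            "objects": [{"kind": ob.spec.kind, "bbox": _bbox_of(ob),
                         "label": ob.label} for ob in truth.objects],
        })

    for i in range(config.n_spreads):
        img, truth = render_metaphase(
            config.n_chromosomes, config.dic_fraction, config.overlap_fraction,
            rng, canvas_shape=config.canvas_100x)
        name = f"spread_{i:03d}.png"
        Image.fromarray(img).save(out / name)
        mask_name = f"spread_{i:03d}_labels.png"
        labels16 = np.zeros(config.canvas_100x, dtype=np.uint16)
        for j, ob in enumerate(truth.objects, start=1):
            r0, c0, r1, c1 = ob.bbox
            sub = labels16[r0:r1, c0:c1]
            sub[ob.mask] = j
        Image.fromarray(labels16).save(out / mask_name)
        manifest["images"].append({
            "path": name, "magnification": "100x", "label_mask": mask_name,
            "objects": [{"kind": ob.spec.kind, "bbox": _bbox_of(ob),
                         "label": ob.label} for ob in truth.objects],
        })

    if config.n_tiles:
        tiles, labels = make_tile_dataset(config.n_tiles,
                                          config.non_dic_to_dic_ratio, rng)
        tdir = out / "tiles"
        tdir.mkdir(exist_ok=True)
        entries = []
        for i, (tile, lab) in enumerate(zip(tiles, labels)):
            name = f"tiles/tile_{i:05d}.png"
            Image.fromarray(tile).save(out / name)
            entries.append({"path": name, "magnification": "100x",
                            "objects": [{"kind": "tile", "bbox": [0, 0, *tile.shape[:2]],
                                         "label": "DIC" if lab == 1 else "non-DIC"}]})
        manifest["images"].extend(entries)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
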