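"""Width/hole features against brute-force oracles, the published triage
rule table, and watershed mass-splitting properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage
from skimage.draw import disk as draw_disk

from conftest import as_object
from dicascade.synthetic import make_adhesive_pair
from dicascade.triage import (SegmenterConfig, TriageRule, count_holes,
                              measure_width, segment_mass, triage,
                              triage_objects)


# ---------------------------------------------------------------------- WH

def brute_force_min_rect_short_side(mask: np.ndarray,
                                    n_angles: int = 1440) -> float:
    """Dense angle scan of the minimum-area enclosing rectangle over the
    pixel-corner cloud; returns the short side of the best rectangle."""
    coords = np.argwhere(mask).astype(float)
    corners = np.concatenate([coords + off for off in
                              ([0, 0], [0, 1], [1, 0], [1, 1])])
    best_area, best_short = np.inf, np.inf
    for a in np.linspace(0, np.pi / 2, n_angles, endpoint=False):
        u = np.array([np.sin(a), np.cos(a)])
        v = np.array([np.cos(a), -np.sin(a)])
        pu, pv = corners @ u, corners @ v
        ext = (pu.max() - pu.min(), pv.max() - pv.min())
        area = ext[0] * ext[1]
        if area < best_area:
            best_area, best_short = area, min(ext)
    return best_short


def test_width_axis_aligned_rectangle():
    mask = np.zeros((30, 60), dtype=bool)
    mask[10:20, 5:45] = True                      # 10 x 40
    assert measure_width(mask) == 10


def test_width_rotated_rectangle():
    from skimage.draw import polygon

    a = np.deg2rad(30)
    R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    corners = np.array([[0, 0], [10, 0], [10, 40], [0, 40]], float) @ R.T + 60
    rr, cc = polygon(corners[:, 0], corners[:, 1])
    mask = np.zeros((120, 120), dtype=bool)
    mask[rr, cc] = True
    assert abs(measure_width(mask) - 10) <= 1


def test_width_single_pixel_and_empty():
    assert measure_width(np.ones((1, 1), bool)) == 1
    with pytest.raises(ValueError):
        measure_width(np.zeros((5, 5), bool))


def test_width_matches_brute_force_on_random_polyominoes():
    rng = np.random.default_rng(23)
    for _ in range(100):
        mask = np.zeros((40, 40), dtype=bool)
        r, c = 20, 20
        for _ in range(rng.integers(5, 120)):
            mask[r, c] = True
            r = int(np.clip(r + rng.integers(-1, 2), 1, 38))
            c = int(np.clip(c + rng.integers(-1, 2), 1, 38))
        oracle = brute_force_min_rect_short_side(mask)
        assert abs(measure_width(mask) - oracle) <= 1


# ---------------------------------------------------------------------- IH

def flood_fill_hole_count(mask: np.ndarray) -> int:
    """Oracle: 4-connected background components not reachable from the
    border of the padded crop."""
    padded = np.pad(mask, 1)
    bg = ~padded
    labels, n = ndimage.label(bg, structure=np.array([[0, 1, 0],
                                                      [1, 1, 1],
                                                      [0, 1, 0]]))
    border = set(labels[0, :]) | set(labels[-1, :]) | \
        set(labels[:, 0]) | set(labels[:, -1])
    border.discard(0)
    return sum(1 for lab in range(1, n + 1) if lab not in border)


def test_hole_count_disk_and_annulus():
    rr, cc = np.ogrid[:50, :50]
    filled = (rr - 25) ** 2 + (cc - 25) ** 2 <= 15 ** 2
    assert count_holes(filled) == 0
    annulus = filled & ~((rr - 25) ** 2 + (cc - 25) ** 2 <= 7 ** 2)
    assert count_holes(annulus) == 1
    with pytest.raises(ValueError):
        count_holes(np.zeros((5, 5), bool))


def test_hole_count_matches_flood_fill_oracle():
    rng = np.random.default_rng(31)
    for _ in range(80):
        mask = ndimage.binary_closing(
            rng.random((30, 30)) < 0.55, structure=np.ones((2, 2)))
        if not mask.any():
            continue
        assert count_holes(mask) == flood_fill_hole_count(mask)


# ------------------------------------------------------------------- rules

@pytest.mark.parametrize("wh,ih,expected", [
    (24, 0, "impurity"),     # too narrow
    (40, 4, "impurity"),     # too many holes
    (1, 0, "impurity"),
    (70, 1, "mass"),         # too wide
    (66, 0, "mass"),
    (66, 4, "impurity"),     # impurity rule wins over width
    (40, 1, "individual"),
    (25, 3, "individual"),   # inclusive boundaries
    (65, 3, "individual"),
    (25, 0, "individual"),
])
def test_triage_rule_table(wh, ih, expected):
    assert triage(wh, ih) == expected


@settings(max_examples=200, deadline=None)
@given(st.integers(min_value=1, max_value=500),
       st.integers(min_value=0, max_value=50))
def test_triage_is_total_partition(wh, ih):
    rule = TriageRule()
    cat = triage(wh, ih, rule)
    assert cat in ("impurity", "mass", "individual")
    expect_impurity = wh < rule.wh_min or ih > rule.ih_max
    expect_mass = not expect_impurity and wh > rule.wh_max
    assert cat == ("impurity" if expect_impurity
                   else "mass" if expect_mass else "individual")


def test_triage_rule_validation():
    with pytest.raises(ValueError):
        TriageRule(wh_min=70, wh_max=65)
    with pytest.raises(ValueError):
        triage(0, 0)


# --------------------------------------------------------------- watershed

def two_disks(r, gap, shape=(140, 180)):
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_disk((shape[0] // 2, shape[1] // 2 - (2 * r - gap) // 2), r,
                       shape=shape)
    mask[rr, cc] = True
    rr, cc = draw_disk((shape[0] // 2, shape[1] // 2 + (2 * r - gap) // 2), r,
                       shape=shape)
    mask[rr, cc] = True
    return mask


def test_overlapping_large_disks_split_in_two():
    mask = two_disks(30, 20)      # centers 40 px apart
    segs = segment_mass(as_object(mask))
    assert len(segs) == 2
    assert sum(s.area for s in segs) == mask.sum()


def test_convex_blob_stays_whole():
    rr, cc = np.ogrid[:80, :80]
    blob = (rr - 40) ** 2 + (cc - 40) ** 2 <= 25 ** 2
    assert len(segment_mass(as_object(blob))) == 1


def test_tiny_seeds_never_split():
    """Seed regions below the 150 px threshold are filtered, so small
    touching disks come back unsplit."""
    mask = two_disks(6, 1, shape=(40, 60))
    assert len(segment_mass(as_object(mask))) == 1


def test_raising_seed_threshold_is_monotone():
    mask = two_disks(30, 20)
    counts = []
    for area in (10, 150, 400, 10_000):
        cfg = SegmenterConfig(min_seed_area=area)
        counts.append(len(segment_mass(as_object(mask), cfg)))
    assert counts == sorted(counts, reverse=True)
    assert counts[-1] == 1


def test_partition_property_on_adhesive_pairs():
    for seed in range(15):
        mass, _ = make_adhesive_pair(np.deg2rad(60 + 2 * seed), seed)
        segs = segment_mass(as_object(mass))
        total = np.zeros_like(mass, dtype=np.int32)
        for s in segs:
            r0, c0, r1, c1 = s.bbox
            total[r0:r1, c0:c1] += s.mask_crop
        assert (total[mass] == 1).all() and (total[~mass] == 0).all()


def test_cross_pairs_split_at_moderate_angles():
    """Paired chromosomes crossing at >=60 degrees split into 2 for at
    least 80% of seeds (high-crossover masses are allowed to fail)."""
    rng = np.random.default_rng(42)
    split = 0
    for seed in range(50):
        ang = rng.uniform(np.pi / 3, np.pi / 2)
        mass, _ = make_adhesive_pair(ang, seed)
        split += len(segment_mass(as_object(mass))) == 2
    assert split >= 40


def test_triage_objects_resplits_masses():
    mass, _ = make_adhesive_pair(np.deg2rad(85), 5)
    out = triage_objects([as_object(mass)])
    assert len(out) == 2
    assert all(ob.category in ("individual", "impurity", "mass") for ob in out)
    assert all(ob.parent_mass_id == 1 for ob in out)
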