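"""Fidelity of the synthetic Giemsa-spread generator: hole counts match
centromere counts, rendered widths track the request, scenes and corpora
are seed-deterministic."""

import json

import numpy as np
import pytest

from dicascade.synthetic import (CorpusConfig, PlacementError, generate_corpus,
                                 make_chromosome, plan_spread,
                                 plan_tile_labels, render_field_10x,
                                 render_metaphase, render_object, _tight_crop)
from dicascade.triage import count_holes, measure_width


def _render(spec):
    return _tight_crop(*render_object(spec))[0]


@pytest.mark.parametrize("kind,expected_ih",
                         [("monocentric", 0), ("dicentric", 1), ("tricentric", 2)])
def test_hole_count_matches_centromere_count(kind, expected_ih):
    """A body with k centromeres encloses k-1 holes (0 for general
    chromosomes, 1 for dicentrics, 2 for tricentrics) in >=95% of renders,
    and the measured WH stays within +/-3 px of the requested width."""
    rng = np.random.default_rng(17)
    ih_ok = wh_ok = 0
    n = 100
    for _ in range(n):
        w = float(rng.uniform(26, 60))
        spec = make_chromosome(kind, float(rng.uniform(90, 200)), w,
                               float(rng.uniform(-0.12, 0.12)), rng)
        mask = _render(spec)
        ih_ok += count_holes(mask) == expected_ih
        wh_ok += abs(measure_width(mask) - round(w)) <= 3
    assert ih_ok >= 0.95 * n
    assert wh_ok >= 0.95 * n


def test_width_outside_range_rejected():
    with pytest.raises(ValueError):
        make_chromosome("monocentric", 150, 10.0, 0.0, 0)
    with pytest.raises(ValueError):
        make_chromosome("monocentric", 150, 80.0, 0.0, 0)
    with pytest.raises(ValueError):
        make_chromosome("pentacentric", 150, 40.0, 0.0, 0)


def test_disjoint_spread_has_disjoint_masks_and_no_dic():
    image, truth = render_metaphase(46, 0.0, 0.0, seed=3)
    assert image.dtype == np.uint8 and image.shape[-1] == 3
    assert len(truth.objects) == 46
    assert all(ob.label == "non-DIC" for ob in truth.objects)
    # pairwise disjoint: total painted area equals sum of individual areas
    canvas = np.zeros(image.shape[:2], dtype=np.int32)
    for ob in truth.objects:
        r0, c0, r1, c1 = ob.bbox
        canvas[r0:r1, c0:c1] += ob.mask
    assert canvas.max() == 1


def test_expected_dic_count_tracks_fraction():
    """Mean DIC count per 46-chromosome spread is ~46 * dic_fraction."""
    rng = np.random.default_rng(5)
    total = sum(plan_spread(46, 1 / 46, rng).count("dicentric")
                for _ in range(200))
    # Binomial(200*46, 1/46): mean 200, sd ~14
    assert abs(total - 200) < 45


def test_overlap_creates_adhesive_masses():
    from scipy import ndimage

    image, truth = render_metaphase(20, 0.0, 0.2, seed=11,
                                    canvas_shape=(900, 900))
    members = [ob for ob in truth.objects if ob.label == "mass-member"]
    assert members
    union = np.zeros(image.shape[:2], dtype=bool)
    for ob in truth.objects:
        r0, c0, r1, c1 = ob.bbox
        union[r0:r1, c0:c1] |= ob.mask
    labels, _ = ndimage.label(union, structure=np.ones((3, 3), int))
    for ob in members:
        comp = labels[int(ob.centroid[0]), int(ob.centroid[1])]
        assert comp > 0
        assert (labels == comp).sum() > ob.mask.sum()


def test_field_centroid_bookkeeping():
    _, truth = render_field_10x(0, 4, 5, seed=2)
    assert truth.metaphase_centroids == []
    _, truth = render_field_10x(3, 5, 5, seed=2)
    assert len(truth.metaphase_centroids) == 3


def test_metaphases_are_pore_like_nuclei_blocky():
    """Inside a metaphase cluster box much of the area is background
    (pore-like); inside a nucleus box it is not (blocky)."""
    from dicascade.locator import binarize_otsu

    image, truth = render_field_10x(2, 2, 0, seed=9)
    fg = binarize_otsu(image)
    for r, c in truth.metaphase_centroids:
        box = fg[int(r) - 30:int(r) + 30, int(c) - 30:int(c) + 30]
        meta_bg = 1.0 - box.mean()
        for ob in truth.objects:
            if ob.spec.kind != "nucleus":
                continue
            r0, c0, r1, c1 = ob.bbox
            nuc_bg = 1.0 - fg[r0:r1, c0:c1].mean()
            assert meta_bg > nuc_bg


def test_tile_label_ratio():
    rng = np.random.default_rng(0)
    for ratio in (45.0, 70.0):
        labels = plan_tile_labels(10_000, ratio, rng)
        expected = 10_000 / (ratio + 1.0)
        sd = np.sqrt(expected)
        assert abs(labels.sum() - expected) < 4 * sd


def test_corpus_manifest_deterministic(tmp_path):
    cfg = CorpusConfig(n_fields=1, n_spreads=1, n_chromosomes=8,
                       n_tiles=4, canvas_10x=(520, 520), canvas_100x=(500, 500))
    generate_corpus(cfg, tmp_path / "a", seed=7)
    generate_corpus(cfg, tmp_path / "b", seed=7)
    ma = (tmp_path / "a" / "manifest.json").read_bytes()
    mb = (tmp_path / "b" / "manifest.json").read_bytes()
    assert ma == mb
    manifest = json.loads(ma)
    assert manifest["seed"] == 7
    assert len(manifest["images"]) == 1 + 1 + 4


def test_canvas_too_small_raises():
    with pytest.raises(PlacementError):
        render_metaphase(30, 0.0, 0.0, seed=0, canvas_shape=(250, 250))
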