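"""Metaphase-cell locating on 10x field images.

Metaphase spreads look "pore-like" (many thin strokes), nuclei and debris
"blocky-like".  The locator binarizes the field with Otsu's threshold,
removes the pore-like texture with a morphological opening, subtracts the
blocky remainder from the original binarization, cleans up what is left
and dilates it into compact candidate blobs whose centroids are reported.
A candidate spread is later screened by its chromosome object count
(46 +/- 3 accepted, adhesive clusters and acentric fragments allowed for).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from ._morph import disk_closing, disk_dilation, disk_opening


class DegenerateImageError(ValueError):
    """Image has a degenerate histogram (fewer than two gray levels)."""


@dataclass
class LocatorParams:
    se_radius: int = 4          # opening disk: > half a 10x stroke width
    cleanup_radius: int = 4     # closing (fuse strokes) + opening (drop specks)
    highlight_radius: int = 12  # final dilation merging a cluster into one blob
    min_area: int = 200         # px; smaller blobs are debris


@dataclass
class MetaphaseCandidate:
    centroid: tuple[float, float]       # (row, col), 0-based
    bbox: tuple[int, int, int, int]     # half-open (r0, c0, r1, c1)
    area_px: int


def binarize_otsu(image: np.ndarray) -> np.ndarray:
    """Foreground = pixels at or below the Otsu threshold (the between-class
    variance maximizer; the darker class)."""
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("field image must be single-channel")
    if np.unique(image).size < 2:
        raise DegenerateImageError("constant image: Otsu threshold undefined")
    t = threshold_otsu(image)
    return image <= t


def suppress_pore_texture(mask: np.ndarray, se_radius: int = 4) -> np.ndarray:
    """Morphological opening with a disk: thin strokes vanish, blocky
    regions (nuclei, large impurities) survive."""
    if se_radius < 1:
        raise ValueError("se_radius must be >= 1")
    return disk_opening(mask, se_radius)


def candidate_mask(original: np.ndarray, suppressed: np.ndarray,
                   cleanup_radius: int = 4, highlight_radius: int = 12,
                   speck_radius: int = 2) -> np.ndarray:
    """Subtract the blocky content, tidy the remainder, highlight clusters.

    Set-subtraction ``original \\ suppressed``, then (when
    ``cleanup_radius`` > 0) a closing that fuses neighbouring strokes
    followed by a small opening (``speck_radius``) that drops isolated
    debris specks, then (when ``highlight_radius`` > 0) a dilation that
    turns each stroke cluster into one compact candidate blob.  With both
    radii zero the result is the exact set difference.
    """
    original = np.asarray(original, dtype=bool)
    suppressed = np.asarray(suppressed, dtype=bool)
    if original.shape != suppressed.shape:
        raise ValueError("mask dimensions differ")
    out = original & ~suppressed
    if cleanup_radius > 0:
        out = disk_opening(disk_closing(out, cleanup_radius), speck_radius)
    if highlight_radius > 0:
        out = disk_dilation(out, highlight_radius)
    return out


def locate_metaphases(image: np.ndarray,
                      params: LocatorParams | None = None) -> list[MetaphaseCandidate]:
    """Full locating chain: Otsu -> opening -> subtraction/cleanup ->
    8-connected components -> centroids, dropping sub-minimum blobs."""
    params = params or LocatorParams()
    binary = binarize_otsu(image)
    suppressed = suppress_pore_texture(binary, params.se_radius)
    cleaned = candidate_mask(binary, suppressed, params.cleanup_radius, 0)
    cand = candidate_mask(cleaned, np.zeros_like(cleaned), 0,
                          params.highlight_radius)
    labels, n = ndimage.label(cand, structure=np.ones((3, 3), dtype=int))
    out: list[MetaphaseCandidate] = []
    if n == 0:
        return out
    slices = ndimage.find_objects(labels)
    for lab, sl in enumerate(slices, start=1):
        region = labels[sl] == lab
        area = int(region.sum())
        if area < params.min_area:
            continue
        # centroid of the stroke content, not of the inflated blob
        content = region & cleaned[sl]
        rr, cc = np.nonzero(content if content.any() else region)
        centroid = (float(rr.mean()) + sl[0].start, float(cc.mean()) + sl[1].start)
        bbox = (sl[0].start, sl[1].start, sl[0].stop, sl[1].stop)
        out.append(MetaphaseCandidate(centroid=centroid, bbox=bbox, area_px=area))
    return out


def screen_spread(object_count: int, center: int = 46, tolerance: int = 3) -> bool:
    """Accept a spread iff its object count lies in 46 +/- 3 (inclusive)."""
    if object_count < 0:
        raise ValueError("object_count must be >= 0")
    return center - tolerance <= object_count <= center + tolerance
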