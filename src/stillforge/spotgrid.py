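"""Threshold/area spot finding on raster images and the two-parameter
grid search over (minimum spot area, minimum spot height).

The background of a diffraction image is estimated robustly (median and
MAD, immune to the spots themselves); pixels exceeding
background + min_height·σ are grouped by 8-connectivity and components of
at least min_area pixels become spots.  The grid search scores every
threshold pair against reference spot positions with an F1 score
(match radius 2 px) and reports the score matrix as a heat map, breaking
ties toward the most conservative (largest) thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = ["Spot", "GridSearchResult", "find_spots", "grid_search_spot_params"]

MATCH_RADIUS_PX = 2.0


@dataclass
class Spot:
    """Connected component above threshold: intensity-weighted centroid
    (pixel coordinates, x = column, y = row), area and peak height in σ."""

    x: float
    y: float
    area: int
    height: float


@dataclass
class GridSearchResult:
    scores: np.ndarray  # (n_area, n_height)
    areas: np.ndarray
    heights: np.ndarray
    best_area: int
    best_height: float
    best_score: float


def find_spots(image: np.ndarray, min_height: float = 3.0, min_area: int = 2) -> list[Spot]:
    """Deterministic threshold spot finder.

    background = median(image); σ = 1.4826·MAD.  A flat (zero-MAD) image
    yields no spots rather than an error.
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("empty image")
    background = float(np.median(image))
    sigma = 1.4826 * float(np.median(np.abs(image - background)))
    if sigma == 0.0:
        sigma = float(np.std(image))
        if sigma == 0.0:
            return []
    mask = image > background + min_height * sigma
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return []
    spots: list[Spot] = []
    excess = np.clip(image - background, 0.0, None)
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        comp = labels[sl] == lab
        area = int(comp.sum())
        if area < min_area:
            continue
        w = excess[sl] * comp
        total = w.sum()
        ys, xs = np.mgrid[sl[0], sl[1]]
        cy = float((w * ys).sum() / total)
        cx = float((w * xs).sum() / total)
        peak = float((image[sl][comp].max() - background) / sigma)
        spots.append(Spot(x=cx, y=cy, area=area, height=peak))
    return spots


def _f1_score(found: list[Spot], reference: np.ndarray, radius: float = MATCH_RADIUS_PX) -> float:
    """One-to-one greedy matching within ``radius`` px, then F1."""
    if len(found) == 0:
        return 0.0
    pos = np.array([[s.x, s.y] for s in found])
    tree = cKDTree(reference)
    dists, idx = tree.query(pos, distance_upper_bound=radius)
    used: set[int] = set()
    tp = 0
    for d, j in sorted(zip(dists, idx)):
        if not np.isfinite(d) or j in used:
            continue
        used.add(int(j))
        tp += 1
    precision = tp / len(found)
    recall = tp / len(reference)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def grid_search_spot_params(
    image: np.ndarray,
    reference_positions: np.ndarray,
    area_range: tuple[int, int] = (2, 22),
    height_range: tuple[int, int] = (2, 15),
) -> GridSearchResult:
    """Exhaustive (min_area, min_height) grid search scored by F1 against
    known reference positions.  Ties break toward larger min_area, then
    larger min_height (the most conservative optimum)."""
    reference_positions = np.asarray(reference_positions, dtype=float).reshape(-1, 2)
    if len(reference_positions) == 0:
        raise ValueError("empty reference position set")
    areas = np.arange(area_range[0], area_range[1] + 1)
    heights = np.arange(height_range[0], height_range[1] + 1)
    scores = np.zeros((len(areas), len(heights)))
    # spots depend on height only; filter by area afterwards
    for jh, h in enumerate(heights):
        spots_h = find_spots(image, min_height=float(h), min_area=1)
        for ja, a in enumerate(areas):
            subset = [s for s in spots_h if s.area >= a]
            scores[ja, jh] = _f1_score(subset, reference_positions)
    best = scores.max()
    ja, jh = max(
        ((ja, jh) for ja in range(len(areas)) for jh in range(len(heights))
         if scores[ja, jh] >= best - 1e-12),
        key=lambda t: (areas[t[0]], heights[t[1]]),
    )
    return GridSearchResult(
        scores=scores,
        areas=areas,
        heights=heights,
        best_area=int(areas[ja]),
        best_height=float(heights[jh]),
        best_score=float(best),
    )


def write_heatmap(result: GridSearchResult, path) -> None:
    """Score matrix as a tab-separated table (rows = min_area)."""
    with open(path, "w") as fh:
        fh.write("min_area\\min_height\t" + "\t".join(str(h) for h in result.heights) + "\n")
        for a, row in zip(result.areas, result.scores):
            fh.write(str(a) + "\t" + "\t".join(f"{v:.4f}" for v in row) + "\n")
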