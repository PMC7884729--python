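"""From probability maps to particle coordinates.

The protein-probability plane is thresholded; small fragments are
dropped; components whose centroids fall within one particle diameter
of each other are merged (single-link, transitive) because a particle's
image may come out fragmented; each merged group yields one particle at
the area-weighted centroid of its pixels, scored by the mean protein
probability over the group.  The decision threshold is tuned by
sweeping a grid and keeping the value with the best particle-level F1
against ground-truth coordinates, ties resolved to the higher threshold
(fewer contaminant picks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage import measure

from .evalmetrics import PRCurve, f1_score, particle_match
from .io_formats import CLASS_PROTEIN, ParticleSet

__all__ = [
    "PickParams",
    "protein_mask",
    "extract_particles",
    "tune_threshold",
    "pick_micrograph",
]


@dataclass
class PickParams:
    """Picking parameters.

    ``min_fragment_px`` defaults to 5% of the particle disk area (tiny
    speckle rejection) when left at 0.
    """

    particle_radius_px: int
    prob_threshold: float = 0.5
    min_fragment_px: int = 0

    def __post_init__(self) -> None:
        if self.particle_radius_px < 1:
            raise ValueError("particle_radius_px must be >= 1")
        if not (0.0 <= self.prob_threshold <= 1.0):
            raise ValueError("prob_threshold must be in [0, 1]")
        if self.min_fragment_px < 0:
            raise ValueError("min_fragment_px must be >= 0")
        if self.min_fragment_px == 0:
            self.min_fragment_px = max(1, int(round(0.05 * math.pi * self.particle_radius_px ** 2)))


def protein_mask(prob: np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask where P(protein) >= threshold (inclusive)."""
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must be in [0, 1]")
    prob = np.asarray(prob)
    plane = prob[:, :, CLASS_PROTEIN] if prob.ndim == 3 else prob
    return plane >= threshold


def extract_particles(
    mask: np.ndarray,
    params: PickParams,
    prob: Optional[np.ndarray] = None,
) -> ParticleSet:
    """Merge mask fragments into particles and estimate their centres.

    Components below ``min_fragment_px`` are dropped; remaining
    components are merged transitively when their centroids are within
    ``2 * particle_radius_px``; each group becomes one particle at the
    area-weighted centroid of all its pixels.  When ``prob`` is given,
    particles are scored with the mean protein probability over the
    group's pixels.
    """
    mask = np.asarray(mask).astype(bool)
    h, w = mask.shape
    lab, n = measure.label(mask, connectivity=2, return_num=True)
    if n == 0:
        return ParticleSet(centers=np.empty((0, 2)), radius_px=params.particle_radius_px,
                           image_shape=(h, w), scores=np.empty(0))
    areas = np.bincount(lab.ravel())[1:]
    keep = np.nonzero(areas >= params.min_fragment_px)[0] + 1
    if len(keep) == 0:
        return ParticleSet(centers=np.empty((0, 2)), radius_px=params.particle_radius_px,
                           image_shape=(h, w), scores=np.empty(0))
    # component centroids (x, y) and areas
    ys, xs = np.nonzero(mask)
    labs = lab[ys, xs]
    cents = []
    comp_areas = []
    for c in keep:
        sel = labs == c
        cents.append((xs[sel].mean(), ys[sel].mean()))
        comp_areas.append(sel.sum())
    cents = np.array(cents)
    comp_areas = np.array(comp_areas, dtype=float)
    # single-link transitive merge by centroid distance
    m = len(keep)
    parent = list(range(m))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    limit = 2.0 * params.particle_radius_px
    d = np.hypot(cents[:, None, 0] - cents[None, :, 0], cents[:, None, 1] - cents[None, :, 1])
    for i in range(m):
        for j in range(i + 1, m):
            if d[i, j] <= limit:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(m):
        groups.setdefault(find(i), []).append(i)

    plane = None
    if prob is not None:
        prob = np.asarray(prob)
        plane = prob[:, :, CLASS_PROTEIN] if prob.ndim == 3 else prob

    centers = []
    scores = []
    for members in groups.values():
        w_total = comp_areas[members].sum()
        cx = float((cents[members, 0] * comp_areas[members]).sum() / w_total)
        cy = float((cents[members, 1] * comp_areas[members]).sum() / w_total)
        centers.append((min(max(cx, 0.0), w - 1.0), min(max(cy, 0.0), h - 1.0)))
        if plane is not None:
            sel = np.isin(lab[ys, xs], keep[members])
            scores.append(float(plane[ys[sel], xs[sel]].mean()))
        else:
            scores.append(1.0)
    order = np.lexsort((np.array(centers)[:, 0], np.array(centers)[:, 1]))
    centers = np.array(centers)[order]
    scores = np.array(scores)[order]
    return ParticleSet(centers=centers, radius_px=params.particle_radius_px,
                       image_shape=(h, w), scores=scores)


def pick_micrograph(prob: np.ndarray, params: PickParams) -> ParticleSet:
    """Threshold the protein plane and extract particles in one call."""
    mask = protein_mask(prob, params.prob_threshold)
    return extract_particles(mask, params, prob=prob)


def tune_threshold(
    probs: Sequence[np.ndarray],
    truths: Sequence[ParticleSet],
    params: PickParams,
    grid: Sequence[float],
    tol_px: Optional[float] = None,
) -> tuple[float, PRCurve]:
    """Sweep the probability threshold and return the F1-optimal value.

    For each grid threshold, particles are picked from every probability
    map and matched to the corresponding ground truth within ``tol_px``
    (default: one particle radius); counts are pooled over the images.
    Returns the argmax-F1 threshold (ties to the higher threshold) and
    the full PR curve.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be nonempty")
    if np.any(np.diff(grid) < 0):
        raise ValueError("grid must be ascending")
    if len(probs) != len(truths):
        raise ValueError("probs and truths length mismatch")
    if all(len(t) == 0 for t in truths):
        raise ValueError("empty truth everywhere: F1 undefined")
    tol = tol_px if tol_px is not None else float(params.particle_radius_px)
    precisions, recalls, counts = [], [], []
    best_f1 = -1.0
    best_t = grid[0]
    for t in grid:
        tp = fp = fn = 0
        for prob, truth in zip(probs, truths):
            mask = protein_mask(prob, float(t))
            picked = extract_particles(mask, params, prob=prob)
            tpi, fpi, fni, _ = particle_match(picked, truth, tol)
            tp, fp, fn = tp + tpi, fp + fpi, fn + fni
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        precisions.append(prec)
        recalls.append(rec)
        counts.append((tp, fp, fn))
        f1 = f1_score(prec, rec)
        if f1 >= best_f1:  # ties go to the higher (later) threshold
            best_f1 = f1
            best_t = float(t)
    curve = PRCurve(thresholds=grid, precision=np.array(precisions),
                    recall=np.array(recalls), counts=counts)
    return best_t, curve
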