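"""Ensemble nuclear segmentation: score, bucket, and select candidates.

A single-parameter cell segmenter run across a sweep of expected radii
produces an ensemble of candidate regions.  Each candidate C is scored by
three appearance efficiencies capturing the nuclear model (convex, brighter
inside than outside, with a crisp boundary):

    e_convex(C)     = |C| / |convex hull of C|
    e_boundary(C)   = 1 - mean over boundary pixels of (R - T)
    e_background(C) = mean(I - T over C) / mean(I - T over background)

where I is the normalized [0, 1] intensity image, T an adaptive-threshold
image, R the maximal intensity in the 3x3 (3x3x3) neighborhood of each
boundary pixel, and the background is the complement of all candidate
supports.  The total score is the sum of the three terms.

Overlapping candidates are grouped into buckets (connected components of
the overlap graph) and within each bucket a greedy maximizer picks a
non-overlapping subset by descending score.  Detection quality against a
ground-truth mask is reported as IoU-matched precision/recall/F1.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .core import ConfigurationError, DataError

__all__ = [
    "CandidateSegmentation",
    "OverlapBucket",
    "DetectionScore",
    "adaptive_threshold",
    "convex_efficiency",
    "boundary_efficiency",
    "background_efficiency",
    "score_candidate",
    "candidates_from_label_mask",
    "bucket_overlaps",
    "greedy_select",
    "detection_f1",
    "ensemble_segment",
]


@dataclass
class CandidateSegmentation:
    """One candidate region with its efficiency terms and total score."""

    id: int
    mask: np.ndarray                  # boolean, full image frame
    source_radius: float | None = None
    e_convex: float | None = None
    e_boundary: float | None = None
    e_background: float | None = None
    score: float | None = None

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class OverlapBucket:
    """A connected component of the candidate-overlap graph."""

    members: list[int]
    pixel_support: np.ndarray

    def __post_init__(self) -> None:
        self.members = sorted(self.members)


@dataclass
class DetectionScore:
    precision: float
    recall: float
    f1: float
    matches: list[tuple[int, int, float]] = field(default_factory=list)


def adaptive_threshold(image: np.ndarray, window: int = 31,
                       offset: float = 0.1) -> np.ndarray:
    """Local-mean adaptive threshold: mean over a window minus an offset.

    The offset must exceed the halo deficit bright objects leave in the
    local mean around them, so that the background excess I - T stays
    positive on average; otherwise the background-efficiency denominator
    changes sign and inverts every score.
    """
    return ndi.uniform_filter(np.asarray(image, dtype=float),
                              size=window, mode="reflect") - offset


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise DataError("empty candidate region")
    return mask


def convex_efficiency(mask: np.ndarray) -> float:
    """Region area over convex-hull area, on the pixel (voxel) grid.

    The hull is the discrete convex hull image of the mask, so a convex
    filled region scores exactly 1.  Degenerate one-pixel-wide regions,
    whose hull image can collapse onto the region itself, are floored at
    the region area and also score 1.
    """
    from skimage.morphology import convex_hull_image

    mask = _check_mask(mask)
    # crop to the bounding box; hull computation is local to the region
    slices = ndi.find_objects(mask.astype(np.uint8))[0]
    local = mask[slices]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hull = convex_hull_image(local)
    hull_area = max(int(hull.sum()), int(local.sum()))
    return float(local.sum()) / hull_area


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    """Region pixels 8- (26-) adjacent to a non-region pixel."""
    full = np.ones((3,) * mask.ndim)
    interior = ndi.binary_erosion(mask, structure=full, border_value=0)
    return mask & ~interior


def boundary_efficiency(mask: np.ndarray, image: np.ndarray,
                        thresh: np.ndarray) -> float:
    """1 - mean(R - T) over the boundary of the region.

    R is the maximal image intensity in the region surrounding each
    boundary pixel — its full-connectivity 3x3 (3x3x3) neighborhood
    restricted to pixels *outside* the candidate — and T the
    adaptive-threshold value at the boundary pixel.  The appearance model
    expects a bright interior against a dark exterior: a correctly placed
    boundary has exterior surroundings at or below threshold (score near
    1), while a boundary cutting through a bright interior sees R - T
    large and scores low.
    """
    mask = _check_mask(mask)
    image = np.asarray(image, dtype=float)
    if mask.shape != image.shape:
        raise DataError("mask and image shapes differ")
    if mask.all():
        raise DataError("region has no boundary (covers the whole frame)")
    boundary = _boundary_pixels(mask)
    outside = np.where(mask, -np.inf, image)
    exterior_max = ndi.maximum_filter(outside, size=3, mode="constant",
                                      cval=-np.inf)
    diff = exterior_max[boundary] - np.asarray(thresh, dtype=float)[boundary]
    # frame-edge boundary pixels may have their only exterior neighbors
    # outside the frame; they carry no intensity evidence and are skipped
    diff = diff[np.isfinite(diff)]
    if diff.size == 0:
        raise DataError("boundary has no in-frame exterior neighborhood")
    return float(1.0 - diff.mean())


def background_efficiency(mask: np.ndarray, image: np.ndarray,
                          thresh: np.ndarray,
                          background: np.ndarray | None = None,
                          eps: float = 1e-6, cap: float = 100.0) -> float:
    """Ratio of above-threshold excess inside the region vs the background.

    ``background`` defaults to the complement of the region; the ensemble
    driver passes the complement of all candidate supports.  A near-zero
    denominator (background sitting exactly at threshold) caps the
    efficiency at ``cap`` with a warning.
    """
    mask = _check_mask(mask)
    image = np.asarray(image, dtype=float)
    thresh = np.asarray(thresh, dtype=float)
    if background is None:
        background = ~mask
    background = np.asarray(background, dtype=bool)
    if not background.any():
        raise DataError("empty background")
    num = float((image[mask] - thresh[mask]).mean())
    den = float((image[background] - thresh[background]).mean())
    if abs(den) < eps:
        warnings.warn("background excess ~ 0; capping background efficiency",
                      stacklevel=2)
        return cap
    return num / den


def score_candidate(cand: CandidateSegmentation, image: np.ndarray,
                    thresh: np.ndarray,
                    background: np.ndarray | None = None
                    ) -> CandidateSegmentation:
    """Fill in the three efficiencies and the total score (their sum)."""
    cand.e_convex = convex_efficiency(cand.mask)
    cand.e_boundary = boundary_efficiency(cand.mask, image, thresh)
    cand.e_background = background_efficiency(cand.mask, image, thresh,
                                              background)
    cand.score = cand.e_convex + cand.e_boundary + cand.e_background
    return cand


def candidates_from_label_mask(label_mask: np.ndarray,
                               source_radius: float | None = None,
                               start_id: int = 0
                               ) -> list[CandidateSegmentation]:
    """Split a label mask (0 = background) into candidate regions."""
    label_mask = np.asarray(label_mask)
    out = []
    next_id = start_id
    for lab in np.unique(label_mask):
        if lab == 0:
            continue
        out.append(CandidateSegmentation(next_id, label_mask == lab,
                                         source_radius))
        next_id += 1
    return out


def _overlap(a: CandidateSegmentation, b: CandidateSegmentation,
             min_fraction: float = 0.0) -> bool:
    inter = int((a.mask & b.mask).sum())
    if inter == 0:
        return False
    if min_fraction <= 0.0:
        return True
    return inter / min(a.area, b.area) >= min_fraction


def bucket_overlaps(candidates: Sequence[CandidateSegmentation],
                    min_fraction: float = 0.0) -> list[OverlapBucket]:
    """Connected components of the overlap graph (edge: shared pixels).

    Uses a pixel-ownership stack to find intersecting pairs without the
    quadratic mask sweep, then union-find for the components.
    """
    n = len(candidates)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    if n:
        stack = np.stack([c.mask for c in candidates])
        cover = stack.sum(axis=0)
        multi = np.argwhere(cover > 1)
        pairs = set()
        for coord in multi:
            owners = np.flatnonzero(stack[(slice(None), *coord)])
            for a in range(len(owners)):
                for b in range(a + 1, len(owners)):
                    pairs.add((int(owners[a]), int(owners[b])))
        for i, j in pairs:
            if _overlap(candidates[i], candidates[j], min_fraction):
                union(i, j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    buckets = []
    for members in groups.values():
        support = np.zeros_like(candidates[members[0]].mask)
        for i in members:
            support |= candidates[i].mask
        buckets.append(OverlapBucket(members, support))
    buckets.sort(key=lambda b: b.members[0])
    return buckets


def greedy_select(candidates: Sequence[CandidateSegmentation],
                  min_fraction: float = 0.0) -> list[CandidateSegmentation]:
    """Greedy maximum-score non-overlapping subset.

    Repeatedly takes the highest-scoring remaining candidate and discards
    everything overlapping it.  Ties break toward the larger region, then
    the smaller id — fully deterministic.
    """
    for c in candidates:
        if c.score is None:
            raise DataError(f"candidate {c.id} is not scored")
    order = sorted(candidates, key=lambda c: (-c.score, -c.area, c.id))
    chosen: list[CandidateSegmentation] = []
    for cand in order:
        if not any(_overlap(cand, kept, min_fraction) for kept in chosen):
            chosen.append(cand)
    return chosen


def _regions_from(arg) -> list[np.ndarray]:
    if isinstance(arg, np.ndarray) and not arg.dtype == object:
        if arg.dtype == bool:
            return [arg]
        return [arg == lab for lab in np.unique(arg) if lab != 0]
    out = []
    for item in arg:
        if isinstance(item, CandidateSegmentation):
            out.append(item.mask)
        else:
            out.append(np.asarray(item, dtype=bool))
    return out


def detection_f1(selected, truth, iou_threshold: float = 0.5
                 ) -> DetectionScore:
    """IoU-matched detection precision/recall/F1.

    ``selected`` and ``truth`` may be label masks or lists of boolean
    regions.  Pairs are matched one-to-one greedily by descending IoU,
    keeping only pairs with IoU >= the threshold.
    """
    pred = _regions_from(selected)
    true = _regions_from(truth)
    if not pred or not true:
        return DetectionScore(0.0, 0.0, 0.0)
    ious = []
    for i, p in enumerate(pred):
        pa = int(p.sum())
        for j, t in enumerate(true):
            inter = int((p & t).sum())
            if inter == 0:
                continue
            union = pa + int(t.sum()) - inter
            iou = inter / union
            if iou >= iou_threshold:
                ious.append((iou, i, j))
    ious.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    matches = []
    for iou, i, j in ious:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        matches.append((i, j, iou))
    tp = len(matches)
    precision = tp / len(pred)
    recall = tp / len(true)
    f1 = 0.0 if tp == 0 else 2 * precision * recall / (precision + recall)
    return DetectionScore(precision, recall, f1, matches)


def ensemble_segment(image: np.ndarray,
                     candidate_masks: dict[float, np.ndarray] | Sequence[np.ndarray],
                     window: int = 31, offset: float = 0.1,
                     min_fraction: float = 0.0
                     ) -> tuple[np.ndarray, dict]:
    """Full ensemble pipeline: score, bucket, greedily select, relabel.

    ``candidate_masks`` maps each radius parameter to the label mask its
    segmentation produced (or is a plain sequence of label masks).  Returns
    the final non-overlapping uint16 label mask and a per-bucket report.
    """
    image = np.asarray(image, dtype=float)
    if image.max() > 1.0:
        image = image / image.max()
    thresh = adaptive_threshold(image, window=window, offset=offset)

    candidates: list[CandidateSegmentation] = []
    if isinstance(candidate_masks, dict):
        items = sorted(candidate_masks.items())
    else:
        items = [(None, m) for m in candidate_masks]
    for radius, mask in items:
        if np.asarray(mask).shape != image.shape:
            raise DataError(
                f"candidate mask shape {np.asarray(mask).shape} does not "
                f"match image shape {image.shape} (radius={radius})")
        candidates.extend(candidates_from_label_mask(
            mask, radius, start_id=len(candidates)))

    final = np.zeros(image.shape, dtype=np.uint16)
    if not candidates:
        warnings.warn("no candidate regions; returning an empty mask",
                      stacklevel=2)
        return final, {"buckets": [], "n_candidates": 0}

    support = np.zeros(image.shape, dtype=bool)
    for c in candidates:
        support |= c.mask
    background = ~support
    if not background.any():
        raise DataError("candidates cover the whole frame; no background")
    for c in candidates:
        score_candidate(c, image, thresh, background)

    by_id = {c.id: c for c in candidates}
    report = {"n_candidates": len(candidates), "buckets": []}
    label = 1
    for bucket in bucket_overlaps(candidates, min_fraction):
        scored = [by_id[i] for i in bucket.members]
        chosen = greedy_select(scored, min_fraction)
        for c in chosen:
            final[c.mask] = label
            label += 1
        report["buckets"].append({
            "members": bucket.members,
            "scores": {c.id: round(float(c.score), 6) for c in scored},
            "chosen": [c.id for c in chosen],
        })
    return final, report
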