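"""Seeded generators for every synthetic input class the pipelines consume.

All generators are pure functions of (parameters, seed): the same seed gives
bit-identical output.  Three families are provided:

* labeled 2-D Gaussian mixtures — K unit-covariance normals spaced along the
  x-axis, the standard benchmark for cluster-number estimation;
* string sets — single-bit-flip families and noisy template classes, the
  byte-string analogue of an image digit set;
* cell images — bright filled ellipses on a dark noisy background with a
  ground-truth label mask, plus candidate segmentations generated per radius
  parameter that over-segment at small radii and merge at large radii,
  emulating a single-parameter cell segmenter run across a radius sweep.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .core import ConfigurationError, DataError, ObjectSet

__all__ = [
    "SimConfig",
    "gaussian_mixture",
    "euclidean_delta",
    "trimmed_mean_distance",
    "bitflip_string_set",
    "template_class_strings",
    "cell_image",
    "CellScene",
]


@dataclass
class SimConfig:
    """Validated simulation request: kind, per-kind parameters, seed."""

    kind: str
    parameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    KINDS = ("gaussian_mixture", "string_set", "cell_image")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ConfigurationError(
                f"unknown simulation kind {self.kind!r}; one of {self.KINDS}")


def gaussian_mixture(K: int = 3, r: float = 1.0, n_per_cluster: int = 500,
                     seed: int | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """K 2-D standard normals centered at (i*r, 0), i = 0..K-1.

    Returns (points, labels) with K * n_per_cluster rows.  Identity
    covariance throughout; ``r`` is the center spacing in units of the
    cluster standard deviation.
    """
    if K < 1 or n_per_cluster < 1 or r <= 0:
        raise ConfigurationError("need K >= 1, n_per_cluster >= 1, r > 0")
    rng = np.random.default_rng(seed)
    pts, labels = [], []
    for i in range(K):
        p = rng.standard_normal((n_per_cluster, 2))
        p[:, 0] += i * r
        pts.append(p)
        labels.append(np.full(n_per_cluster, i))
    return np.concatenate(pts), np.concatenate(labels)


def euclidean_delta(cluster_points: np.ndarray, x: np.ndarray,
                    centroid: np.ndarray | None = None) -> float:
    """Euclidean stand-in for the complexity difference K(A) - K(x).

    The deficiency of point x within cluster A is approximated by the
    distance from x to the centroid of A.
    """
    cluster_points = np.atleast_2d(np.asarray(cluster_points, dtype=float))
    if cluster_points.shape[0] == 0:
        raise DataError("empty cluster")
    c = cluster_points.mean(axis=0) if centroid is None else np.asarray(centroid)
    return float(np.linalg.norm(np.asarray(x, dtype=float) - c))


def trimmed_mean_distance(cluster_points: np.ndarray,
                          centroid: np.ndarray | None = None,
                          trim: str = "radial_sd") -> float:
    """Mean centroid distance over the points within one SD of the centroid.

    ``trim="radial_sd"`` keeps points whose centroid distance is at most the
    standard deviation of all member distances; ``trim="rms"`` uses the
    root-mean-square spread (sqrt of mean squared centroid distance), which
    equals the per-axis SD for an isotropic cluster; ``trim="none"``
    disables trimming.  If trimming would discard every point the nearest
    point is retained as a floor.  Single-point clusters return 0.
    """
    pts = np.atleast_2d(np.asarray(cluster_points, dtype=float))
    if pts.shape[0] == 0:
        raise DataError("empty cluster")
    c = pts.mean(axis=0) if centroid is None else np.asarray(centroid, dtype=float)
    d = np.linalg.norm(pts - c, axis=1)
    if pts.shape[0] == 1:
        return 0.0
    if trim == "none":
        return float(d.mean())
    if trim == "radial_sd":
        s = float(d.std())
    elif trim == "rms":
        s = float(np.sqrt(np.mean(d * d)))
    else:
        raise ConfigurationError(f"unknown trim rule {trim!r}")
    keep = d <= s + 1e-12
    if not keep.any():
        keep = d == d.min()
    return float(d[keep].mean())


def bitflip_string_set(template: str, n: int) -> ObjectSet:
    """n bit strings, the i-th equal to the template with bit i flipped."""
    if set(template) - {"0", "1"}:
        raise DataError("template must be a bit string")
    if n > len(template):
        raise DataError("n may not exceed the template length")
    flips = []
    for i in range(n):
        b = "1" if template[i] == "0" else "0"
        flips.append(template[:i] + b + template[i + 1:])
    return ObjectSet(flips, [f"flip{i:03d}" for i in range(n)])


def template_class_strings(n_classes: int = 2, per_class: int = 50,
                           length: int = 1024, noise_rate: float = 0.05,
                           seed: int | None = None,
                           alphabet_sizes: Sequence[int] | None = None
                           ) -> tuple[ObjectSet, np.ndarray]:
    """Noisy byte-string classes around seeded random templates.

    Each class has a seeded random template drawn over its own byte
    alphabet; each object is its class template with every byte
    independently resampled (uniformly over the class alphabet) with
    probability ``noise_rate``.

    Classes use alphabets of different sizes (default: log-spaced between 4
    and 256 symbols), so objects of different classes differ systematically
    in compressed size — the byte-level analogue of visual classes whose
    members differ in complexity, which is what compression-based
    deficiencies respond to.
    """
    if not 0 <= noise_rate < 0.5:
        raise ConfigurationError("noise_rate must be in [0, 0.5)")
    if alphabet_sizes is None:
        alphabet_sizes = np.unique(np.geomspace(4, 256, n_classes)
                                   .round().astype(int))
        if alphabet_sizes.size < n_classes:  # tiny n_classes collisions
            alphabet_sizes = np.linspace(4, 256, n_classes).round().astype(int)
    if len(alphabet_sizes) != n_classes:
        raise ConfigurationError("need one alphabet size per class")
    rng = np.random.default_rng(seed)
    objects, ids, labels = [], [], []
    for c, a in enumerate(alphabet_sizes):
        symbols = rng.permutation(256)[:int(a)].astype(np.uint8)
        template = rng.choice(symbols, size=length)
        for j in range(per_class):
            arr = template.copy()
            mask = rng.random(length) < noise_rate
            arr[mask] = rng.choice(symbols, size=int(mask.sum()))
            objects.append(arr.tobytes())
            ids.append(f"c{c}_{j:03d}")
            labels.append(c)
    return ObjectSet(objects, ids), np.array(labels)


# ---------------------------------------------------------------------------
# synthetic cell scenes
# ---------------------------------------------------------------------------

@dataclass
class CellScene:
    """A synthetic nuclear image with ground truth and candidate masks."""

    image: np.ndarray                     # float in [0, 1]
    truth: np.ndarray                     # uint16 labels, 0 = background
    candidates: dict[float, np.ndarray]   # radius -> uint16 label mask
    cell_radii: list[float]


def _draw_ellipse(mask: np.ndarray, cy: float, cx: float, ry: float,
                  rx: float, theta: float, label: int) -> None:
    from skimage.draw import ellipse

    rr, cc = ellipse(cy, cx, ry, rx, shape=mask.shape, rotation=theta)
    mask[rr, cc] = label


def cell_image(n_cells: int = 8, radius_range: tuple[float, float] = (6.0, 12.0),
               contrast: float = 0.6, noise_sd: float = 0.05,
               size: tuple[int, int] = (192, 192), seed: int | None = None,
               candidate_radii: Sequence[float] | None = None,
               max_tries: int = 2000) -> CellScene:
    """Bright elliptical nuclei on a dark noisy background.

    Nuclei are placed without overlap (bounded rejection sampling), each
    with semi-axes drawn around a radius from ``radius_range`` and a random
    orientation.  Intensities: background 0.15, nuclei 0.15 + contrast,
    additive Gaussian noise of ``noise_sd``, clipped to [0, 1].

    Candidate segmentations are produced for each radius in
    ``candidate_radii`` (default: five radii spanning the range and beyond)
    by Otsu thresholding followed by watershed splitting seeded at distance
    -transform peaks at least ~2*radius apart: small radii split large
    nuclei apart (over-segmentation), large radii leave touching or nearby
    nuclei merged (under-segmentation).
    """
    from scipy import ndimage as ndi
    from skimage.feature import peak_local_max
    from skimage.filters import threshold_otsu
    from skimage.segmentation import watershed

    rng = np.random.default_rng(seed)
    h, w = size
    truth = np.zeros(size, dtype=np.uint16)
    lo, hi = radius_range
    radii: list[float] = []
    placed = 0
    tries = 0
    centers: list[tuple[float, float, float]] = []
    while placed < n_cells:
        tries += 1
        if tries > max_tries:
            raise DataError(
                f"could not place {n_cells} non-overlapping cells in {size}")
        r = float(rng.uniform(lo, hi))
        # pronounced eccentricity: elongated nuclei are what small-radius
        # segmentations split and large-radius segmentations blur together
        ry = r * float(rng.uniform(0.6, 0.85))
        rx = r * float(rng.uniform(1.15, 1.55))
        rmax = max(ry, rx)
        cy = float(rng.uniform(rmax + 2, h - rmax - 2))
        cx = float(rng.uniform(rmax + 2, w - rmax - 2))
        # min gap of 3 px between nuclei keeps the truth masks disjoint
        if any(math.hypot(cy - py, cx - px) < rmax + pr + 3
               for py, px, pr in centers):
            continue
        theta = float(rng.uniform(0, math.pi))
        placed += 1
        _draw_ellipse(truth, cy, cx, ry, rx, theta, placed)
        centers.append((cy, cx, rmax))
        radii.append(r)

    image = np.full(size, 0.15)
    image[truth > 0] += contrast
    image += rng.normal(0.0, noise_sd, size=size)
    image = np.clip(image, 0.0, 1.0)

    if candidate_radii is None:
        span = hi - lo
        candidate_radii = [lo - 0.4 * span, lo, 0.5 * (lo + hi), hi,
                           hi + 0.4 * span]
        candidate_radii = [max(2.0, round(r, 1)) for r in candidate_radii]

    # shared foreground from a global threshold; the radius parameter only
    # controls how the foreground is split into objects
    fg = image > threshold_otsu(image)
    fg = ndi.binary_opening(fg, structure=np.ones((3, 3)))
    dist = ndi.distance_transform_edt(fg)

    candidates: dict[float, np.ndarray] = {}
    for radius in candidate_radii:
        min_dist = max(2, int(round(1.6 * radius)))
        coords = peak_local_max(dist, min_distance=min_dist, labels=fg,
                                exclude_border=False)
        markers = np.zeros(size, dtype=np.int32)
        for j, (yy, xx) in enumerate(coords, start=1):
            markers[yy, xx] = j
        if markers.max() == 0:
            candidates[float(radius)] = np.zeros(size, dtype=np.uint16)
            continue
        labels = watershed(-dist, markers, mask=fg)
        # drop specks far below the nominal radius for this parameter
        min_area = max(4, int(0.4 * math.pi * radius * radius))
        out = np.zeros(size, dtype=np.uint16)
        nxt = 1
        for lab in range(1, labels.max() + 1):
            m = labels == lab
            if m.sum() >= min_area:
                out[m] = nxt
                nxt += 1
        candidates[float(radius)] = out

    return CellScene(image, truth, candidates, radii)
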