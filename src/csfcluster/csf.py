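"""The cluster structure function (CSF).

For a multiset S and a criterion function f built from per-part optimality
deficiencies, the CSF is

    H_S^f(k) = min over partitions pi of S into k non-empty parts of f(pi),

for k = 1..|S|.  The default criterion is the bandwidth sum: for each part
take max(delta) - min(delta) and add up.  H is monotone non-increasing and
reaches 0 at k = |S| (all singletons); the shape of its descent carries the
cluster structure of S.

Two computation routes are provided:

* :func:`csf_exact` — exhaustive minimization over all set partitions,
  feasible for |S| <= 12 (Bell-number growth).
* :func:`csf_empirical` — the practical pipeline: cluster S once per K
  (spectral clustering on an NCD matrix by default), repeatedly subsample
  5*K objects, evaluate per-cluster deficiencies on the subsample, and
  aggregate with the log-bandwidth form

      H(K) = sum over occupied clusters of log2(max d - min d + 1) / Kmax,

  reporting the mean and standard deviation over subsamples.  The empirical
  curve is the product of several heuristics and is not forced monotone.

:func:`csf_points` is the numeric-data variant where the complexity
difference K(A) - K(x) is approximated by the Euclidean distance of x to the
centroid of its cluster.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Callable, Iterator, Sequence

import numpy as np

from .compress import Compressor, CompressorSpec
from .core import DataError, ObjectSet, as_object_list
from .deficiency import SizeOracle, part_deltas, sigma_trim

__all__ = [
    "Partition",
    "CSFCurve",
    "CSFExactResult",
    "enumerate_partitions",
    "criterion_bandwidth_sum",
    "csf_exact",
    "csf_exact_curve",
    "csf_sigma",
    "csf_empirical",
    "csf_points",
    "eq5_log_bandwidth",
    "MAX_EXACT_N",
]

MAX_EXACT_N = 12


@dataclass(frozen=True)
class Partition:
    """A partition of {0..n-1} into k non-empty unlabeled parts."""

    assignment: tuple[int, ...]

    @property
    def n(self) -> int:
        return len(self.assignment)

    @property
    def k(self) -> int:
        return max(self.assignment) + 1 if self.assignment else 0

    def parts(self) -> list[tuple[int, ...]]:
        out: list[list[int]] = [[] for _ in range(self.k)]
        for i, p in enumerate(self.assignment):
            out[p].append(i)
        return [tuple(p) for p in out]


@dataclass
class CSFCurve:
    """Per-K mean and standard deviation of the structure-function value."""

    k_values: np.ndarray
    mean_H: np.ndarray
    std_H: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.mean_H = np.asarray(self.mean_H, dtype=float)
        self.std_H = np.asarray(self.std_H, dtype=float)
        if not (self.k_values.size == self.mean_H.size == self.std_H.size):
            raise DataError("curve arrays must share length")
        if np.any(self.std_H < 0):
            raise DataError("negative standard deviation")

    def to_dict(self) -> dict:
        return {"k": self.k_values.tolist(), "mean": self.mean_H.tolist(),
                "std": self.std_H.tolist(), "n_samples": int(self.n_samples)}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"k": self.k_values, "mean": self.mean_H,
                             "std": self.std_H})


@dataclass
class CSFExactResult:
    value: float
    witness: Partition


# ---------------------------------------------------------------------------
# exhaustive route
# ---------------------------------------------------------------------------

def enumerate_partitions(n: int, k: int,
                         max_n: int = MAX_EXACT_N) -> Iterator[Partition]:
    """Yield every partition of {0..n-1} into exactly k non-empty parts.

    Uses restricted-growth strings, so each unlabeled partition appears
    exactly once; S(n, k) partitions total (Stirling numbers of the second
    kind).  Guarded at ``max_n`` because the count grows like the Bell
    numbers.
    """
    if not 1 <= k <= n:
        raise DataError(f"need 1 <= k <= n, got k={k}, n={n}")
    if n > max_n:
        raise DataError(
            f"exact enumeration refused for n={n} > {max_n} "
            "(set partition count grows as the Bell numbers)")

    a = [0] * n  # restricted growth string: a[i] <= max(a[:i]) + 1

    def rec(i: int, used: int) -> Iterator[Partition]:
        if i == n:
            if used == k:
                yield Partition(tuple(a))
            return
        # prune: remaining slots must be able to reach exactly k parts
        if used + (n - i) < k:
            return
        for v in range(used):  # place into an existing part
            a[i] = v
            yield from rec(i + 1, used)
        if used < k:
            a[i] = used
            yield from rec(i + 1, used + 1)

    yield from rec(0, 0)


def criterion_bandwidth_sum(deltas_by_part: Sequence[Sequence[float]]) -> float:
    """Sum over parts of max(delta) - min(delta); the default criterion f.

    Zeroing any deficiency can only shrink a part's bandwidth span, and an
    all-zero assignment gives 0, so this satisfies the criterion-function
    axioms.
    """
    total = 0.0
    for deltas in deltas_by_part:
        d = np.asarray(deltas, dtype=float)
        if d.size == 0:
            raise DataError("empty part in criterion")
        total += float(d.max() - d.min())
    return total


Criterion = Callable[[Sequence[Sequence[float]]], float]


class _PartDeltaCache:
    """Memoizes per-part deficiency vectors across the partition sweep."""

    def __init__(self, objects: list[Any], oracle: SizeOracle):
        self.objects = objects
        self.oracle = oracle
        self._memo: dict[tuple[int, ...], np.ndarray] = {}

    def deltas(self, part_indices: tuple[int, ...]) -> np.ndarray:
        key = tuple(sorted(part_indices))
        if key not in self._memo:
            part = [self.objects[i] for i in key]
            self._memo[key] = part_deltas(part, self.oracle)
        return self._memo[key]


def csf_exact(S: ObjectSet | Sequence[Any], k: int, oracle: SizeOracle,
              criterion: Criterion = criterion_bandwidth_sum) -> CSFExactResult:
    """H_S^f(k) by exhaustive minimization, with a witness partition.

    The witness is the first minimizer in deterministic enumeration order.
    """
    objects = as_object_list(S)
    cache = _PartDeltaCache(objects, oracle)
    best: CSFExactResult | None = None
    for pi in enumerate_partitions(len(objects), k):
        val = criterion([cache.deltas(p) for p in pi.parts()])
        if best is None or val < best.value:
            best = CSFExactResult(val, pi)
    assert best is not None
    return best


def csf_exact_curve(S: ObjectSet | Sequence[Any], oracle: SizeOracle,
                    criterion: Criterion = criterion_bandwidth_sum) -> CSFCurve:
    objects = as_object_list(S)
    n = len(objects)
    vals = [csf_exact(objects, k, oracle, criterion).value
            for k in range(1, n + 1)]
    return CSFCurve(np.arange(1, n + 1), np.array(vals), np.zeros(n), 1)


def csf_sigma(S: ObjectSet | Sequence[Any], k: int, oracle: SizeOracle,
              criterion: Criterion = criterion_bandwidth_sum
              ) -> tuple[CSFExactResult, np.ndarray]:
    """Sigma-trimmed structure function.

    Deficiencies are first computed against the whole set as one part; the
    objects within one population standard deviation of the mean deficiency
    are kept, and the structure function is evaluated on that trimmed set.
    Returns the result and the kept indices.
    """
    objects = as_object_list(S)
    deltas = part_deltas(objects, oracle)
    trimmed = sigma_trim(list(range(len(objects))), deltas)
    kept = [objects[i] for i in trimmed.kept_indices]
    if k > len(kept):
        raise DataError(
            f"k={k} exceeds trimmed set size {len(kept)}")
    return csf_exact(kept, k, oracle, criterion), trimmed.kept_indices


# ---------------------------------------------------------------------------
# empirical route
# ---------------------------------------------------------------------------

def eq5_log_bandwidth(deltas_by_cluster: Sequence[np.ndarray],
                      k_max: int) -> float:
    """Log-bandwidth aggregation of per-cluster deficiencies.

    sum over occupied clusters of log2(max d - min d + 1), divided by Kmax.
    Empty clusters contribute 0 (log2(0 + 1)); the fixed Kmax denominator
    puts curves for different K on a common scale.
    """
    total = 0.0
    for d in deltas_by_cluster:
        if len(d) == 0:
            continue
        d = np.asarray(d, dtype=float)
        total += math.log2(float(d.max() - d.min()) + 1.0)
    return total / k_max


def _subsample_cluster_deltas(objects: list[Any], labels: np.ndarray,
                              idx: np.ndarray, K: int,
                              comp: Compressor,
                              elem_sizes: np.ndarray) -> list[np.ndarray]:
    """Per-cluster deficiency vectors restricted to subsample ``idx``."""
    out: list[np.ndarray] = []
    for p in range(K):
        members = idx[labels[idx] == p]
        if members.size < 2:
            out.append(np.zeros(members.size))
            continue
        zp = comp.size_of_concat([objects[i] for i in members])
        out.append(zp - elem_sizes[members] + math.log2(members.size))
    return out


def csf_empirical(S: ObjectSet | Sequence[Any], Kmax: int,
                  spec: CompressorSpec | None = None, *,
                  n_subsamples: int = 200, seed: int | None = None,
                  labels_by_k: Sequence[np.ndarray] | None = None,
                  sample_factor: int | None = 5,
                  exhaustive: bool = False,
                  criterion: Criterion | None = None) -> CSFCurve:
    """Empirical CSF curve by subsampled clustering.

    By default objects are clustered once per K by spectral clustering on
    the pairwise NCD matrix; each of ``n_subsamples`` draws of 5*K objects
    (without replacement, clamped to |S|) is scored with the log-bandwidth
    aggregation of compressor deficiencies.

    ``exhaustive=True`` replaces the heuristics with the exact machinery
    (exhaustive partition minimization of ``criterion`` under ``oracle``,
    full-set "subsample"), which reproduces :func:`csf_exact` and serves as
    the bridge between the two routes.
    """
    objects = as_object_list(S)
    n = len(objects)
    ks = np.arange(1, Kmax + 1)

    comp = Compressor(spec)
    elem_sizes = np.array([comp.size(o) for o in objects], dtype=float)

    if exhaustive:
        crit = criterion or criterion_bandwidth_sum
        full = np.arange(n)
        vals = []
        for K in ks:
            best = math.inf
            for pi in enumerate_partitions(n, int(K)):
                labels = np.asarray(pi.assignment)
                dbc = _subsample_cluster_deltas(objects, labels, full,
                                                int(K), comp, elem_sizes)
                best = min(best, crit(dbc))
            vals.append(best)
        vals = np.array(vals)
        return CSFCurve(ks, vals, np.zeros_like(vals), 1)

    if labels_by_k is None:
        from .spectral import ncd_matrix, spectral_cluster

        D = ncd_matrix(S, spec)
        labels_by_k = [spectral_cluster(D, int(k), seed=seed) for k in ks]

    rng = np.random.default_rng(seed)
    means, stds = [], []
    for K in ks:
        labels = np.asarray(labels_by_k[K - 1])
        m = n if sample_factor is None else min(sample_factor * int(K), n)
        hs = np.empty(n_subsamples)
        for s in range(n_subsamples):
            idx = rng.choice(n, size=m, replace=False)
            dbc = _subsample_cluster_deltas(objects, labels, idx, int(K),
                                            comp, elem_sizes)
            hs[s] = eq5_log_bandwidth(dbc, Kmax)
        means.append(hs.mean())
        stds.append(hs.std())
    return CSFCurve(ks, np.array(means), np.array(stds), n_subsamples)


def csf_points(points: np.ndarray, Kmax: int, *,
               n_subsamples: int = 100, sample_factor: int | None = 5,
               seed: int | None = None, trim: str = "radial_sd",
               n_init: int = 10) -> CSFCurve:
    """Euclidean-distance CSF for numeric point data.

    Points are clustered once per K with k-means; within each cluster the
    deficiency of a point is approximated by its Euclidean distance to the
    cluster centroid.  Per subsample the per-cluster value is the mean
    distance over the points within one standard deviation of the centroid
    (radial trim; see :func:`csfcluster.synthetic.trimmed_mean_distance`),
    and the curve value is the average across occupied clusters.

    ``sample_factor=None`` evaluates the curve deterministically on the
    full data (one pass, std 0) instead of subsampling — the stable choice
    when the selection rule does not need a spread estimate.
    """
    from sklearn.cluster import KMeans

    from .synthetic import trimmed_mean_distance

    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    rng = np.random.default_rng(seed)
    km_seed = int(rng.integers(2**31 - 1))

    ks = np.arange(1, Kmax + 1)
    means, stds = [], []
    for K in ks:
        km = KMeans(n_clusters=int(K), n_init=n_init,
                    random_state=km_seed).fit(points)
        labels, centers = km.labels_, km.cluster_centers_

        def value(idx: np.ndarray) -> float:
            vals = []
            for p in range(int(K)):
                members = idx[labels[idx] == p]
                if members.size == 0:
                    continue
                vals.append(trimmed_mean_distance(points[members],
                                                  centers[p], trim=trim))
            return float(np.mean(vals)) if vals else 0.0

        if sample_factor is None:
            means.append(value(np.arange(n)))
            stds.append(0.0)
            continue
        m = min(sample_factor * int(K), n)
        hs = np.array([value(rng.choice(n, size=m, replace=False))
                       for _ in range(n_subsamples)])
        means.append(hs.mean())
        stds.append(hs.std())
    n_eff = 1 if sample_factor is None else n_subsamples
    return CSFCurve(ks, np.array(means), np.array(stds), n_eff)
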