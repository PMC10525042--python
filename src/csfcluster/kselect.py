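"""Choosing the number of clusters K from a CSF curve, plus baselines.

Two selection rules come from the method itself:

* the one-SD drop rule — the first K whose curve value falls more than one
  standard deviation below the previous value (the Gap-statistic selection
  convention transplanted to CSF curves);
* the uniform-reference log-ratio D_f(k) = log2 H_N(k) - log2 H_S(k), where
  N is |S| items placed uniformly (midpoints of equal subintervals) over the
  range spanned by S; K is the argmax of D_f.

Gap statistic and AIC/BIC model selection over spherical k-means are
provided as the standard baselines for benchmarking.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import ConfigurationError, DataError, ObjectSet
from .csf import CSFCurve

__all__ = [
    "KSelection",
    "select_one_sd",
    "uniform_reference",
    "select_log_ratio",
    "csf_feature_vector",
    "gap_statistic",
    "aic_bic_select",
    "estimate_k_strings",
    "estimate_k_points",
]


@dataclass
class KSelection:
    """A chosen cluster count with the rule and its per-k diagnostics."""

    chosen_k: int
    rule: str
    diagnostics: np.ndarray = field(default_factory=lambda: np.array([]))

    def to_dict(self) -> dict:
        return {"chosen_k": int(self.chosen_k), "rule": self.rule,
                "diagnostics": np.asarray(self.diagnostics).tolist()}


def select_one_sd(curve: CSFCurve) -> KSelection:
    """First K where the curve drops more than one SD below its predecessor.

    The comparison uses the standard deviation at K-1 (the "previous
    value").  When no qualifying drop exists the selection falls back to
    K = 1, the no-meaningful-clusters answer.
    """
    mean, std = curve.mean_H, curve.std_H
    if mean.size < 2:
        raise DataError("one-SD rule needs a curve with at least two points")
    # diagnostic d(K) = drop into K minus the previous SD; positive => fires
    diag = np.full(mean.size, np.nan)
    diag[1:] = (mean[:-1] - mean[1:]) - std[:-1]
    for i in range(1, mean.size):
        if diag[i] > 0:
            return KSelection(int(curve.k_values[i]), "one_sd", diag)
    return KSelection(1, "one_sd", diag)


def uniform_reference(S: ObjectSet | np.ndarray | Sequence,
                      seed: int | None = None) -> "ObjectSet | np.ndarray":
    """|S| reference items placed uniformly over the range spanned by S.

    1-D numeric data: the range [min, max] is cut into n equal subintervals
    and item i sits at the midpoint of subinterval i.  d-dimensional data:
    the per-dimension midpoint construction is applied on the bounding box,
    using the smallest regular grid with at least n cells, truncated to n
    in row-major order.  Byte-string data: seeded uniform random strings of
    the median length (no numeric range exists).
    """
    if isinstance(S, ObjectSet) or (isinstance(S, Sequence)
                                    and len(S) and isinstance(S[0], (bytes, str))):
        objs = list(S.objects) if isinstance(S, ObjectSet) else list(S)
        lengths = sorted(len(o) for o in objs)
        med = lengths[len(lengths) // 2]
        rng = np.random.default_rng(seed)
        refs = [rng.integers(0, 256, size=med, dtype=np.uint8).tobytes()
                for _ in objs]
        return ObjectSet(refs, [f"ref{i:04d}" for i in range(len(refs))])

    X = np.asarray(S, dtype=float)
    n = X.shape[0]
    if n == 0:
        raise DataError("cannot build a reference for an empty set")
    if X.ndim == 1:
        lo, hi = float(X.min()), float(X.max())
        if hi == lo:
            import warnings

            warnings.warn("zero-width range; all reference items coincide",
                          stacklevel=2)
            return np.full(n, lo)
        width = (hi - lo) / n
        return lo + width * (np.arange(n) + 0.5)
    d = X.shape[1]
    lo, hi = X.min(axis=0), X.max(axis=0)
    g = max(1, math.ceil(n ** (1.0 / d)))
    axes = []
    for j in range(d):
        if hi[j] == lo[j]:
            axes.append(np.full(g, lo[j]))
        else:
            width = (hi[j] - lo[j]) / g
            axes.append(lo[j] + width * (np.arange(g) + 0.5))
    grid = np.stack([a.ravel() for a in np.meshgrid(*axes, indexing="ij")],
                    axis=1)
    return grid[:n]


def select_log_ratio(curve_S: CSFCurve, curve_N: CSFCurve) -> KSelection:
    """K = argmax_k [log2 H_N(k) - log2 H_S(k)] over a shared k grid.

    Only k with both curve values strictly positive enter the argmax (the
    logs are undefined otherwise); ties break to the smallest k.
    """
    if not np.array_equal(curve_S.k_values, curve_N.k_values):
        raise DataError("curves must share their k grid")
    hs, hn = curve_S.mean_H, curve_N.mean_H
    valid = (hs > 0) & (hn > 0)
    diag = np.full(hs.size, np.nan)
    diag[valid] = np.log2(hn[valid]) - np.log2(hs[valid])
    if not valid.any():
        raise DataError("log-ratio selection undefined: no k with both "
                        "curve values positive")
    best = np.nanmax(diag)
    chosen = int(curve_S.k_values[np.flatnonzero(diag == best)[0]])
    return KSelection(chosen, "log_ratio", diag)


def csf_feature_vector(curve: CSFCurve) -> np.ndarray:
    """[mean_H(1..10), std_H(1..10)] — the 20-component classifier input."""
    if curve.k_values.size != 10 or curve.k_values[0] != 1:
        raise DataError("feature vector requires a curve over K = 1..10")
    return np.concatenate([curve.mean_H, curve.std_H])


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------

def _kmeans_inertia(points: np.ndarray, k: int, seed: int | None,
                    n_init: int = 10):
    from sklearn.cluster import KMeans

    km = KMeans(n_clusters=k, n_init=n_init,
                random_state=None if seed is None else int(seed) % (2**31))
    km.fit(points)
    return km


def gap_statistic(points: np.ndarray, Kmax: int, B: int = 10,
                  seed: int | None = None) -> KSelection:
    """Gap statistic with uniform bounding-box references.

    gap(k) = mean_b log(W_k^(b)) - log(W_k) with W_k the within-cluster sum
    of squares from k-means; selection by the one-standard-error rule
    (smallest k with gap(k) >= gap(k+1) - s_{k+1}).
    """
    points = np.asarray(points, dtype=float)
    rng = np.random.default_rng(seed)
    lo, hi = points.min(axis=0), points.max(axis=0)
    n = points.shape[0]

    log_w = np.array([math.log(max(_kmeans_inertia(points, k, seed).inertia_,
                                   1e-300))
                      for k in range(1, Kmax + 1)])
    ref_log_w = np.empty((B, Kmax))
    for b in range(B):
        ref = rng.uniform(lo, hi, size=points.shape)
        ref_seed = int(rng.integers(2**31 - 1))
        for k in range(1, Kmax + 1):
            ref_log_w[b, k - 1] = math.log(
                max(_kmeans_inertia(ref, k, ref_seed).inertia_, 1e-300))
    gap = ref_log_w.mean(axis=0) - log_w
    s = ref_log_w.std(axis=0) * math.sqrt(1.0 + 1.0 / B)

    chosen = Kmax
    for k in range(1, Kmax):
        if gap[k - 1] >= gap[k] - s[k]:
            chosen = k
            break
    return KSelection(chosen, "gap", gap)


def _spherical_kmeans_loglik(points: np.ndarray, km) -> float:
    """Log-likelihood of a spherical Gaussian mixture fitted by k-means."""
    n, d = points.shape
    k = km.n_clusters
    rss = float(km.inertia_)
    var = max(rss / (n * d), 1e-12)
    counts = np.bincount(km.labels_, minlength=k).astype(float)
    counts = counts[counts > 0]
    return (float(np.sum(counts * np.log(counts / n)))
            - 0.5 * n * d * (math.log(2 * math.pi * var) + 1.0))


def aic_bic_select(points: np.ndarray, Kmax: int,
                   seed: int | None = None) -> dict[str, KSelection]:
    """AIC and BIC over spherical k-means fits, K = 1..Kmax.

    Parameter count p = K*d (centers) + K-1 (weights) + 1 (shared
    variance); AIC = 2p - 2 lnL, BIC = p ln n - 2 lnL; the chosen K
    minimizes the criterion.
    """
    points = np.asarray(points, dtype=float)
    n, d = points.shape
    aic = np.empty(Kmax)
    bic = np.empty(Kmax)
    for k in range(1, Kmax + 1):
        km = _kmeans_inertia(points, k, seed)
        ll = _spherical_kmeans_loglik(points, km)
        p = k * d + (k - 1) + 1
        aic[k - 1] = 2 * p - 2 * ll
        bic[k - 1] = p * math.log(n) - 2 * ll
    return {"aic": KSelection(int(np.argmin(aic)) + 1, "aic", aic),
            "bic": KSelection(int(np.argmin(bic)) + 1, "bic", bic)}


# ---------------------------------------------------------------------------
# end-to-end estimators
# ---------------------------------------------------------------------------

def estimate_k_strings(S: ObjectSet | Sequence, Kmax: int, spec=None, *,
                       n_subsamples: int = 200, seed: int | None = None
                       ) -> tuple[KSelection, CSFCurve]:
    """One-SD selection on the empirical compressor CSF of a string set."""
    from .csf import csf_empirical

    curve = csf_empirical(S, Kmax, spec, n_subsamples=n_subsamples, seed=seed)
    return select_one_sd(curve), curve


def estimate_k_points(points: np.ndarray, Kmax: int, *,
                      rule: str = "log_ratio", n_subsamples: int = 100,
                      seed: int | None = None, trim: str = "radial_sd"
                      ) -> tuple[KSelection, CSFCurve]:
    """Estimate K for numeric data with the Euclidean-distance CSF.

    ``rule="log_ratio"`` compares the data curve against the curve of a
    uniform reference placement over the bounding box of the data (the
    D_f(k) argmax), both evaluated deterministically on the full data — an
    argmax over a noisy subsampled curve is needlessly unstable.
    ``rule="one_sd"`` applies the drop rule to the subsampled data curve
    alone (the rule needs the subsample spread).
    """
    from .csf import csf_points

    if rule == "one_sd":
        curve = csf_points(points, Kmax, n_subsamples=n_subsamples,
                           seed=seed, trim=trim)
        return select_one_sd(curve), curve
    if rule == "log_ratio":
        curve = csf_points(points, Kmax, sample_factor=None, seed=seed,
                           trim=trim)
        ref = uniform_reference(points, seed=seed)
        ref_curve = csf_points(ref, Kmax, sample_factor=None, seed=seed,
                               trim=trim)
        return select_log_ratio(curve, ref_curve), curve
    raise ConfigurationError(f"unknown selection rule {rule!r}")
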