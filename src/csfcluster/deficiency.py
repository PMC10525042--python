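"""Optimality deficiency and its summary statistics.

A multiset A containing x is an (algorithmic) sufficient statistic for x
when K(A) + log2|A| = K(x): describing x by the model A plus an index into
A is as cheap as the shortest program for x.  The *optimality deficiency*

    delta(A, x) = K(A) + log2|A| - K(x)        [bits]

measures how far A falls short of that ideal.  In practice K is replaced by
compressed sizes Z, and the estimator carries a small-cardinality branch:
delta is 0 when |A| < 2 (a singleton trivially models its only member), else
Z(A) - Z(x) + log2|A|.  Z is measured in bytes while the log-cardinality
term is in bits; the estimator is used as printed, with no unit conversion —
the log term is tiny against byte sizes and only breaks ties.

Deficiencies may be negative with real compressors (and even in theory for
adversarial models); they are deliberately not clamped.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Any, Callable, Mapping, Protocol, Sequence

import numpy as np

from .compress import Compressor, CompressorSpec
from .core import DataError, object_equal

__all__ = [
    "SizeOracle",
    "CompressorSizeOracle",
    "StubComplexityOracle",
    "DeficiencyProfile",
    "TrimmedSet",
    "optimality_deficiency",
    "part_deltas",
    "part_statistics",
    "profile_partition",
    "sigma_trim",
    "intracluster_probability_bound",
]


class SizeOracle(Protocol):
    """Supplies the (approximate) complexities entering a deficiency."""

    def part_size(self, part: Sequence[Any]) -> float: ...

    def element_size(self, x: Any) -> float: ...


class CompressorSizeOracle:
    """Z-based oracle: part size is the compressed concatenation."""

    def __init__(self, spec: CompressorSpec | None = None):
        self.compressor = Compressor(spec)

    def part_size(self, part: Sequence[Any]) -> float:
        return float(self.compressor.size_of_concat(list(part)))

    def element_size(self, x: Any) -> float:
        return float(self.compressor.size(x))


class StubComplexityOracle:
    """Exact-complexity stand-in for theory tests.

    Element complexities come from a mapping or callable; the part
    complexity defaults to the maximum member complexity (any choice cancels
    in bandwidth-style criteria, which depend only on element complexity
    differences within a part).
    """

    def __init__(self, element: Mapping[Any, float] | Callable[[Any], float],
                 part: Callable[[Sequence[Any]], float] | None = None):
        self._element = element
        self._part = part

    def element_size(self, x: Any) -> float:
        if callable(self._element):
            return float(self._element(x))
        return float(self._element[x])

    def part_size(self, part: Sequence[Any]) -> float:
        if self._part is not None:
            return float(self._part(part))
        return max(self.element_size(x) for x in part)


def optimality_deficiency(part: Sequence[Any], x: Any,
                          sizes: SizeOracle) -> float:
    """Practical optimality deficiency of ``part`` as a model for ``x``.

    Returns 0 for parts of cardinality < 2, otherwise
    Z(part) - Z(x) + log2(|part|).  Raises :class:`DataError` when x is not
    a member of the part.
    """
    if not any(object_equal(e, x) for e in part):
        raise DataError("x is not a member of the part")
    if len(part) < 2:
        return 0.0
    return sizes.part_size(part) - sizes.element_size(x) + math.log2(len(part))


def part_deltas(part: Sequence[Any], sizes: SizeOracle) -> np.ndarray:
    """Deficiency of every member of one part, in order."""
    if len(part) == 0:
        raise DataError("empty part")
    if len(part) < 2:
        return np.zeros(len(part))
    zp = sizes.part_size(part)
    logn = math.log2(len(part))
    return np.array([zp - sizes.element_size(x) + logn for x in part])


@dataclass
class DeficiencyProfile:
    """Per-object deficiencies within an assignment, with part summaries."""

    object_ids: list[str]
    part_index: np.ndarray          # per-object part assignment
    delta: np.ndarray               # per-object deficiency, bits
    per_part_mean: np.ndarray       # mu_A per part
    per_part_bandwidth: np.ndarray  # max - min delta per part

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"object_id": self.object_ids,
                             "part": self.part_index,
                             "delta": self.delta})


def part_statistics(deltas_by_part: Sequence[Sequence[float]]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and bandwidth (max - min; 0 for singletons) per part."""
    means, bands = [], []
    for deltas in deltas_by_part:
        d = np.asarray(deltas, dtype=float)
        if d.size == 0:
            raise DataError("empty part in statistics")
        means.append(float(d.mean()))
        bands.append(float(d.max() - d.min()))
    return np.array(means), np.array(bands)


def profile_partition(object_ids: Sequence[str], part_index: Sequence[int],
                      delta: Sequence[float]) -> DeficiencyProfile:
    part_index = np.asarray(part_index)
    delta = np.asarray(delta, dtype=float)
    if not (len(object_ids) == part_index.size == delta.size):
        raise DataError("mismatched profile lengths")
    parts = np.unique(part_index)
    means, bands = part_statistics([delta[part_index == p] for p in parts])
    return DeficiencyProfile(list(object_ids), part_index, delta, means, bands)


@dataclass
class TrimmedSet:
    """Objects within one (population) standard deviation of the mean delta."""

    kept_ids: list
    kept_indices: np.ndarray
    mu: float
    sigma: float


def sigma_trim(object_ids: Sequence, deltas: Sequence[float]) -> TrimmedSet:
    """Keep the objects whose deficiency lies within sigma of the mean.

    sigma is the population standard deviation (divide by n).  With all
    deltas equal, sigma = 0 and every object is kept (deviations are 0).
    """
    d = np.asarray(deltas, dtype=float)
    if d.size == 0:
        raise DataError("cannot trim an empty set")
    mu = float(d.mean())
    sigma = float(d.std())  # population (ddof=0)
    keep = np.flatnonzero(np.abs(d - mu) <= sigma + 1e-12)
    return TrimmedSet([object_ids[i] for i in keep], keep, mu, sigma)


def intracluster_probability_bound(deltas: Sequence[float]) -> float:
    """Empirical mean of 2^-delta over one part.

    Estimates the expected conditional probability between members of a
    cluster; by the AM-GM inequality it is always >= 2^(-mean delta), so
    tight clusters (small deficiencies) have members that are probable given
    each other.
    """
    d = np.asarray(deltas, dtype=float)
    if d.size == 0:
        raise DataError("empty part")
    return float(np.mean(np.exp2(-d)))
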