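"""Exact and empirical cluster structure functions."""
import itertools
from functools import lru_cache

import numpy as np
import pytest

from csfcluster import (CompressorSizeOracle, DataError, StubComplexityOracle,
                        bitflip_string_set, criterion_bandwidth_sum, csf_exact,
                        csf_empirical, csf_exact_curve, csf_points, csf_sigma,
                        enumerate_partitions, eq5_log_bandwidth,
                        template_class_strings)
from csfcluster.deficiency import part_deltas


@lru_cache(None)
def stirling2(n, k):
    if k == 0:
        return 1 if n == 0 else 0
    if n == 0:
        return 0
    return k * stirling2(n - 1, k) + stirling2(n - 1, k - 1)


def brute_force_partitions(n, k):
    """Independent oracle: all surjective label vectors, canonicalized."""
    seen = set()
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        remap, canon = {}, []
        for v in labels:
            remap.setdefault(v, len(remap))
            canon.append(remap[v])
        seen.add(tuple(canon))
    return seen


@pytest.mark.parametrize("n,k,count", [(3, 2, 3), (4, 2, 7), (5, 3, 25)])
def test_partition_counts(n, k, count):
    assert sum(1 for _ in enumerate_partitions(n, k)) == count


def test_partition_enumeration_matches_brute_force():
    for n in range(1, 7):
        for k in range(1, n + 1):
            got = {p.assignment for p in enumerate_partitions(n, k)}
            assert got == brute_force_partitions(n, k)
            assert len(got) == stirling2(n, k)


def test_partition_guard():
    with pytest.raises(DataError):
        list(enumerate_partitions(13, 2))
    with pytest.raises(DataError):
        list(enumerate_partitions(3, 4))


def test_criterion_axioms(rng):
    # all singletons -> 0; numeric example; all-zero deficiencies -> 0
    assert criterion_bandwidth_sum([[1.0], [5.0], [9.0]]) == 0.0
    assert criterion_bandwidth_sum([[0, 2], [3, 5]]) == 4.0
    assert criterion_bandwidth_sum([[0.0, 0.0], [0.0]]) == 0.0
    # on parts already containing a perfectly modelled member (delta 0),
    # zeroing any further deficiency can only narrow the span
    for _ in range(20):
        part = rng.uniform(0, 20, size=rng.integers(2, 8)).tolist() + [0.0]
        zeroed = list(part)
        zeroed[int(np.argmax(part))] = 0.0
        assert (criterion_bandwidth_sum([zeroed])
                <= criterion_bandwidth_sum([part]) + 1e-12)


def test_csf_exact_zero_at_full_split(small_byte_objects):
    oracle = CompressorSizeOracle()
    n = len(small_byte_objects)
    res = csf_exact(small_byte_objects, n, oracle)
    assert res.value == 0.0
    assert res.witness.k == n


def test_csf_exact_k1_is_whole_set_criterion(small_byte_objects):
    oracle = CompressorSizeOracle()
    res = csf_exact(small_byte_objects, 1, oracle)
    deltas = part_deltas(small_byte_objects, oracle)
    assert res.value == pytest.approx(float(deltas.max() - deltas.min()))


def test_csf_exact_stub_spread_k2():
    # stub complexities K(x_i) = 2i over n = 4: exhaustive brute force over
    # the 7 bipartitions gives 4.0 (contiguous groupings)
    objs = ["a", "b", "c", "d"]
    sizes = {o: 2.0 * (i + 1) for i, o in enumerate(objs)}
    oracle = StubComplexityOracle(sizes)

    def brute(k):
        best = np.inf
        for assign in brute_force_partitions(4, k):
            parts = [[sizes[objs[i]] for i in range(4) if assign[i] == p]
                     for p in range(k)]
            best = min(best, sum(max(p) - min(p) for p in parts))
        return best

    assert csf_exact(objs, 2, oracle).value == pytest.approx(brute(2))
    assert brute(2) == 4.0


def test_csf_monotone_nonincreasing_on_stub_oracles():
    for seed in range(5):
        rng = np.random.default_rng(seed)
        objs = [f"o{i}" for i in range(6)]
        oracle = StubComplexityOracle(
            {o: float(rng.integers(0, 60)) for o in objs})
        curve = csf_exact_curve(objs, oracle)
        assert np.all(np.diff(curve.mean_H) <= 1e-9)
        assert curve.mean_H[-1] == 0.0


def test_bitflip_family_is_flat_zero():
    # single-bit flips of one template share their complexity; every
    # partition has zero bandwidth everywhere
    S = bitflip_string_set("010011", 6)
    oracle = StubComplexityOracle(lambda x: 64.0)
    for k in range(1, 7):
        assert csf_exact(S, k, oracle).value == 0.0


def test_spread_construction_lower_bound():
    # K(x_i) = i*m/n keeps the CSF at >= m/n until the full split
    n, m = 5, 40
    objs = [f"s{i}" for i in range(1, n + 1)]
    oracle = StubComplexityOracle(
        {o: (i + 1) * m / n for i, o in enumerate(objs)})
    for k in range(1, n):
        assert csf_exact(objs, k, oracle).value >= m / n - 1e-9
    assert csf_exact(objs, n, oracle).value == 0.0


def test_csf_sigma_equals_exact_when_deltas_equal():
    objs = ["a", "b", "c", "d"]
    oracle = StubComplexityOracle(lambda x: 32.0)
    for k in range(1, 5):
        res, kept = csf_sigma(objs, k, oracle)
        assert len(kept) == 4
        assert res.value == csf_exact(objs, k, oracle).value


def test_csf_sigma_never_exceeds_exact():
    for seed in range(4):
        rng = np.random.default_rng(seed)
        objs = [f"o{i}" for i in range(8)]
        oracle = StubComplexityOracle(
            {o: float(rng.integers(1, 99)) for o in objs})
        _, kept = csf_sigma(objs, 1, oracle)
        for k in range(1, len(kept) + 1):
            res, _ = csf_sigma(objs, k, oracle)
            assert res.value <= csf_exact(objs, k, oracle).value + 1e-9


def test_csf_sigma_zero_at_trimmed_full_split():
    rng = np.random.default_rng(2)
    objs = [f"o{i}" for i in range(7)]
    oracle = StubComplexityOracle({o: float(rng.integers(1, 99))
                                   for o in objs})
    _, kept = csf_sigma(objs, 1, oracle)
    res, _ = csf_sigma(objs, len(kept), oracle)
    assert res.value == 0.0


def test_eq5_arithmetic():
    # one occupied cluster with bandwidth 7 over Kmax = 10
    assert eq5_log_bandwidth([np.array([1.0, 8.0])], 10) == pytest.approx(0.3)
    # singleton-occupied clusters contribute log2(0 + 1) = 0
    assert eq5_log_bandwidth([np.array([4.0]), np.array([]),
                              np.array([9.0])], 5) == 0.0


def test_eq5_permutation_invariance(rng):
    clusters = [rng.uniform(0, 30, size=rng.integers(1, 6)) for _ in range(4)]
    base = eq5_log_bandwidth(clusters, 10)
    perm = [clusters[i] for i in [2, 0, 3, 1]]
    shuffled = [np.flip(c) for c in perm]
    assert eq5_log_bandwidth(shuffled, 10) == pytest.approx(base)


def test_empirical_curve_separates_two_classes():
    S, _ = template_class_strings(2, 20, 512, 0.05, seed=0)
    curve = csf_empirical(S, 4, n_subsamples=60, seed=0)
    assert curve.mean_H[1] < curve.mean_H[0]
    assert np.all(curve.std_H >= 0)


def test_exhaustive_route_reproduces_exact(small_byte_objects):
    objs = small_byte_objects[:5]
    oracle = CompressorSizeOracle()
    curve = csf_empirical(objs, 5, exhaustive=True)
    exact = [csf_exact(objs, k, oracle).value for k in range(1, 6)]
    assert np.array_equal(curve.mean_H, np.array(exact))


def test_csf_points_deterministic_modes():
    rng = np.random.default_rng(0)
    pts = rng.standard_normal((120, 2))
    full = csf_points(pts, 3, sample_factor=None, seed=1)
    assert np.all(full.std_H == 0.0) and full.n_samples == 1
    a = csf_points(pts, 3, n_subsamples=25, seed=9)
    b = csf_points(pts, 3, n_subsamples=25, seed=9)
    assert np.array_equal(a.mean_H, b.mean_H)
    assert np.array_equal(a.std_H, b.std_H)
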