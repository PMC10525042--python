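"""Candidate scoring, overlap bucketing, greedy selection, detection F1."""
import itertools

import numpy as np
import pytest
from skimage.draw import disk

from csfcluster import (CandidateSegmentation, DataError, adaptive_threshold,
                        background_efficiency, boundary_efficiency,
                        bucket_overlaps, convex_efficiency, detection_f1,
                        ensemble_segment, greedy_select, score_candidate)


def rect_candidate(cid, shape, y0, y1, x0, x1, score=None):
    m = np.zeros(shape, dtype=bool)
    m[y0:y1, x0:x1] = True
    c = CandidateSegmentation(cid, m)
    c.score = score
    return c


# -- efficiencies -----------------------------------------------------------

def test_convex_efficiency_shapes():
    square = np.zeros((20, 20), bool)
    square[5:15, 5:15] = True
    assert convex_efficiency(square) == 1.0

    m = np.zeros((50, 50), bool)
    rr, cc = disk((25, 25), 20)
    m[rr, cc] = True
    assert convex_efficiency(m) == pytest.approx(1.0, abs=0.05)

    plus = np.zeros((9, 9), bool)
    plus[3:6, :] = True
    plus[:, 3:6] = True
    assert convex_efficiency(plus) < 1.0
    assert convex_efficiency(plus) == pytest.approx(30 / 38)  # regression

    line = np.zeros((10, 10), bool)
    line[4, 2:8] = True
    assert convex_efficiency(line) == 1.0  # degenerate floor

    with pytest.raises(DataError):
        convex_efficiency(np.zeros((5, 5), bool))


def test_boundary_efficiency_stub_values():
    shape = (20, 20)
    mask = np.zeros(shape, bool)
    mask[5:15, 5:15] = True
    # exterior uniformly at threshold: R - T = 0 everywhere -> exactly 1
    image = np.where(mask, 0.9, 0.3)
    thresh = np.full(shape, 0.3)
    assert boundary_efficiency(mask, image, thresh) == pytest.approx(1.0)
    # exterior 0.2 above threshold on every boundary pixel -> 0.8
    assert boundary_efficiency(mask, image, thresh - 0.2) == pytest.approx(0.8)


def test_boundary_efficiency_penalizes_cut_through_bright_interior():
    shape = (20, 20)
    image = np.full(shape, 0.1)
    image[5:15, 5:15] = 0.9
    thresh = np.full(shape, 0.3)
    whole = np.zeros(shape, bool)
    whole[5:15, 5:15] = True
    half = whole.copy()
    half[:, 10:] = False
    assert (boundary_efficiency(half, image, thresh)
            < boundary_efficiency(whole, image, thresh))


def test_boundary_efficiency_whole_frame_error():
    full = np.ones((8, 8), bool)
    img = np.ones((8, 8)) * 0.5
    with pytest.raises(DataError):
        boundary_efficiency(full, img, img)


def test_background_efficiency_stub_ratio():
    shape = (10, 10)
    mask = np.zeros(shape, bool)
    mask[2:5, 2:5] = True
    image = np.where(mask, 0.4, 0.1)
    thresh = np.zeros(shape)
    assert background_efficiency(mask, image, thresh) == pytest.approx(4.0)
    # region statistics equal to background statistics -> 1.0
    flat = np.full(shape, 0.25)
    assert background_efficiency(mask, flat, thresh) == pytest.approx(1.0)


def test_background_efficiency_capped_denominator():
    shape = (10, 10)
    mask = np.zeros(shape, bool)
    mask[2:5, 2:5] = True
    image = np.where(mask, 0.4, 0.1)
    thresh = np.where(mask, 0.0, 0.1)  # background exactly at threshold
    with pytest.warns(UserWarning):
        val = background_efficiency(mask, image, thresh, cap=50.0)
    assert val == 50.0


def test_score_is_sum_of_terms_and_deterministic(cell_scene):
    image = cell_scene.image
    thresh = adaptive_threshold(image)
    mask = cell_scene.truth == 1
    c1 = score_candidate(CandidateSegmentation(0, mask), image, thresh)
    c2 = score_candidate(CandidateSegmentation(0, mask), image, thresh)
    assert c1.score == pytest.approx(
        c1.e_convex + c1.e_boundary + c1.e_background)
    assert c1.score == c2.score
    assert c1.e_background > 1.0  # true nucleus far brighter than background


def test_adaptive_threshold_constant_image():
    img = np.full((30, 30), 0.4)
    t = adaptive_threshold(img, window=7, offset=0.1)
    assert np.allclose(img - t, 0.1)


# -- bucketing and selection ------------------------------------------------

def test_bucket_transitive_closure():
    shape = (20, 20)
    a = rect_candidate(0, shape, 0, 5, 0, 5)
    b = rect_candidate(1, shape, 3, 8, 3, 8)
    c = rect_candidate(2, shape, 6, 10, 6, 10)
    d = rect_candidate(3, shape, 15, 18, 15, 18)
    buckets = bucket_overlaps([a, b, c, d])
    memberships = sorted(tuple(x.members) for x in buckets)
    assert memberships == [(0, 1, 2), (3,)]
    supports = [x.pixel_support for x in buckets]
    assert not np.any(supports[0] & supports[1])


def test_buckets_match_brute_force_components(rng):
    shape = (40, 40)
    cands = []
    for i in range(50):
        y, x = rng.integers(0, 32, size=2)
        h, w = rng.integers(2, 8, size=2)
        cands.append(rect_candidate(i, shape, y, y + h, x, x + w))
    buckets = bucket_overlaps(cands)

    # brute-force union-find over all pairs
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(50))
    for i, j in itertools.combinations(range(50), 2):
        if np.any(cands[i].mask & cands[j].mask):
            g.add_edge(i, j)
    expect = sorted(sorted(c) for c in nx.connected_components(g))
    assert sorted(b.members for b in buckets) == expect


def test_greedy_prefers_higher_score_and_keeps_disjoint():
    shape = (10, 10)
    a = rect_candidate(0, shape, 0, 5, 0, 5, score=2.5)
    b = rect_candidate(1, shape, 3, 8, 3, 8, score=2.0)
    chosen = greedy_select([a, b])
    assert [c.id for c in chosen] == [0]

    c = rect_candidate(2, shape, 0, 2, 8, 10, score=1.0)
    chosen = greedy_select([a, b, c])
    assert sorted(x.id for x in chosen) == [0, 2]
    for x, y in itertools.combinations(chosen, 2):
        assert not np.any(x.mask & y.mask)


def test_greedy_requires_scores():
    a = rect_candidate(0, (5, 5), 0, 2, 0, 2)
    with pytest.raises(DataError):
        greedy_select([a])


def exhaustive_best(cands):
    """Oracle: max-total-score non-overlapping subset by enumeration."""
    best = 0.0
    for r in range(len(cands) + 1):
        for combo in itertools.combinations(cands, r):
            if any(np.any(a.mask & b.mask)
                   for a, b in itertools.combinations(combo, 2)):
                continue
            best = max(best, sum(c.score for c in combo))
    return best


def test_greedy_never_beats_exhaustive(rng):
    shape = (20, 20)
    for _ in range(20):
        cands = []
        for i in range(int(rng.integers(3, 8))):
            y, x = rng.integers(0, 14, size=2)
            h, w = rng.integers(2, 7, size=2)
            cands.append(rect_candidate(i, shape, y, y + h, x, x + w,
                                        score=float(rng.uniform(0.5, 5))))
        got = sum(c.score for c in greedy_select(cands))
        assert got <= exhaustive_best(cands) + 1e-9


# -- detection and the driver -----------------------------------------------

def test_detection_f1_identity_and_disjoint(cell_scene):
    truth = cell_scene.truth
    assert detection_f1(truth, truth).f1 == 1.0
    shifted = np.zeros_like(truth)
    shifted[:, :5] = 99  # one bogus region away from everything
    assert detection_f1(shifted, truth).f1 == 0.0


def test_detection_f1_split_fails_threshold():
    truth = np.zeros((20, 20), dtype=np.uint16)
    truth[5:15, 5:15] = 1
    halves = np.zeros_like(truth)
    halves[5:15, 5:9] = 1
    halves[5:15, 11:15] = 2
    d = detection_f1(halves, truth, iou_threshold=0.5)
    assert d.recall == 0.0 and d.f1 == 0.0


def test_ensemble_segment_outputs_disjoint_labels(cell_scene):
    final, report = ensemble_segment(cell_scene.image, cell_scene.candidates)
    assert final.dtype == np.uint16
    assert report["n_candidates"] > 0
    labels = np.unique(final)
    assert labels[0] == 0 or final.min() > 0
    # labels are a contiguous relabeling of a non-overlapping selection
    chosen = [c for b in report["buckets"] for c in b["chosen"]]
    assert len(chosen) == final.max()


def test_ensemble_segment_no_candidates_warns():
    img = np.full((32, 32), 0.2)
    empty = np.zeros((32, 32), dtype=np.uint16)
    with pytest.warns(UserWarning):
        final, report = ensemble_segment(img, [empty])
    assert final.max() == 0 and report["n_candidates"] == 0


def test_ensemble_segment_shape_mismatch():
    img = np.full((32, 32), 0.2)
    bad = np.zeros((16, 16), dtype=np.uint16)
    bad[4:8, 4:8] = 1
    with pytest.raises(DataError):
        ensemble_segment(img, [bad])
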