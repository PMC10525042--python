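# Methods

## Model

The package clusters a finite multiset `S` of digital objects by asking, for
each part of a candidate partition, how good a *model* the part is for each
of its members.  The yardstick is the optimality deficiency

    δ(A, x) = K(A) + log2|A| − K(x)   [bits],

where `K` is prefix Kolmogorov complexity: δ is how many bits are wasted by
describing `x` as "the element with this index in multiset A" instead of
optimally.  δ = 0 means `A` is an algorithmic sufficient statistic for `x`.
A criterion function `f` maps a partition's deficiencies to a score; the
default is the bandwidth sum, Σ over parts of (max δ − min δ), which is 0
exactly when each part models all its members equally well.  The cluster
structure function

    H_S^f(k) = min over partitions of S into k non-empty parts of f(π)

is monotone non-increasing with H(|S|) = 0; cluster structure appears as a
sharp descent of the curve at the natural part count.  A σ-trimmed variant
first discards objects whose whole-set deficiency is more than one
population standard deviation from the mean deficiency, then evaluates the
structure function on the trimmed set; it never exceeds the plain value
and is less outlier-driven.

A probabilistic reading backs the criterion: within a part, the empirical
mean of 2^−δ lower-bounds (via AM–GM, by 2^−mean δ) the expected
conditional probability of one member given another, so parts with small
deficiencies contain objects that are probable given each other.  The
function `intracluster_probability_bound` computes this diagnostic.

## Practical estimators

`K` is uncomputable and is approximated from above by the compressed size
`Z` of a real lossless compressor (deflate, bzip2, lzma for byte streams;
PNG for grayscale image arrays, concatenated by vertical stacking).  The
working deficiency estimator is

    δ(A, x) = 0                          if |A| < 2
            = Z(A) − Z(x) + log2|A|      otherwise,

with `Z(A)` the compressed size of the concatenation of the part's
members.  Units: `Z` is in bytes while the log-cardinality term is in
bits; the estimator is used as printed, without unit conversion — the log
term is tiny against byte sizes and only breaks ties.  Negative values are
possible with real compressors and are deliberately not clamped.

Within one part, `Z(A)` and `log2|A|` are constant across members, so the
part's deficiency *bandwidth* reduces to the spread of individual
compressed sizes.  Bandwidth-style criteria therefore respond to grouping
objects of similar intrinsic complexity — which is also why the synthetic
string generator gives its classes distinct per-class compressibility (see
below).

Exhaustive minimization enumerates set partitions via restricted-growth
strings (S(n, k) partitions, each exactly once) and is guarded at n ≤ 12.
The practical pipeline replaces it with three heuristics:

1. pairwise NCD matrix, `NCD(x, y) = (Z(xy) − min(Z(x), Z(y))) /
   max(Z(x), Z(y))`, symmetrized by averaging both concatenation orders
   (real compressors are order-sensitive; downstream spectral clustering
   needs exact symmetry);
2. spectral clustering per K: Gaussian affinity `exp(−D² / 2σ²)` with σ =
   median off-diagonal distance, symmetric-normalized Laplacian, top-K
   eigenvectors row-normalized to unit length, seeded k-means with 10
   restarts;
3. subsampling: per draw, 5·K objects uniformly without replacement;
   deficiencies are evaluated per cluster restricted to the subsample and
   aggregated as Σ over occupied clusters of log2(max δ − min δ + 1),
   divided by Kmax (the fixed denominator puts curves across K on one
   scale; empty and singleton clusters contribute log2(1) = 0).  The curve
   reports the mean and population standard deviation over draws.

Empirical curves are not forced monotone; non-monotonicity is a fingerprint
of the heuristics, and the selection rules only use the descent.  An
`exhaustive=True` mode runs the same per-cluster delta machinery over all
enumerated partitions with the bandwidth-sum criterion and reproduces the
exact structure function bit-for-bit — the bridge used to validate the
pipeline against the exact route.

For numeric point data, `K(A) − K(x)` is approximated by the Euclidean
distance of `x` to the centroid of its k-means cluster; the per-cluster
value is the mean distance over points within one standard deviation of
the centroid, averaged across clusters.  "Within one SD" is read radially:
points whose centroid distance is at most the standard deviation of all
member distances (a `trim` knob also offers the RMS-spread radius or no
trimming; if the trim would discard everything the nearest point is
retained).  For selection by the log-ratio rule the curves are evaluated
deterministically on the full data — an argmax over a subsample-noisy
curve only degrades selection, and the numeric variant needs no spread
estimate.

## Choosing K

Two rules are provided, reflecting two views of the same curve:

* **one-SD rule** — smallest K ≥ 2 with mean(K−1) − mean(K) >
  std(K−1); fallback K = 1 (the no-meaningful-clusters answer) when no
  drop qualifies.  Adding a constant to the curve does not change the
  selection.
* **log-ratio rule** — `D_f(k) = log2 H_N(k) − log2 H_S(k)` against a
  uniform reference `N`: |S| items at the midpoints of |S| equal
  subintervals of [min S, max S] in 1-D, the per-dimension midpoint grid
  (smallest regular grid with ≥ n cells, truncated to n in row-major
  order) for d-dimensional data, and seeded uniform random strings of the
  median length for byte-string data, where no numeric range exists.  K is
  the argmax of D over the k where both curve values are strictly
  positive; ties break to the smallest k.

Baselines for benchmarking: the Gap statistic (uniform bounding-box
references, log within-cluster dispersion, one-standard-error selection)
and AIC/BIC over spherical k-means fits with the classification
log-likelihood (parameter count K·d + K − 1 + 1).  A 20-component feature
vector [mean_H(1..10), std_H(1..10)] is exported for plugging any
off-the-shelf classifier on top of the curves; classifier training is out
of scope.

## Ensemble segmentation

Candidates from segmentations run at several expected radii are scored by

    e_C = e_convex + e_boundary + e_background,

* `e_convex` = region area / discrete convex-hull area (degenerate
  one-pixel-wide regions are floored at the region area and score 1);
* `e_boundary` = 1 − mean over boundary pixels of (R − T), with boundary =
  region pixels 8- (26-) adjacent to the exterior, T the adaptive
  threshold at the boundary pixel, and R the maximal intensity in the
  3×3 (3×3×3) neighborhood *outside* the candidate.  The appearance model
  expects a bright interior against a dark exterior; restricting R to the
  exterior is what lets the term separate a correct boundary (exterior at
  or below threshold, score ≈ 1) from a cut through a bright interior
  (score low).  Taking R over the full neighborhood would always include
  interior pixels and the term would not discriminate;
* `e_background` = mean(I − T) over the region / mean(I − T) over the
  background (complement of all candidate supports).  The ratio is
  unbounded above and is only guarded: |denominator| < 1e−6 caps the value
  (default 100) with a warning.

The adaptive threshold is a local mean over a 31-pixel window minus an
offset, default 0.1 on [0, 1]-normalized images.  The offset must exceed
the halo that bright objects leave in the local mean around them —
otherwise the background excess changes sign and inverts every score —
and 0.1 keeps `e_background` on the same few-units scale as the other two
terms, so no single term dominates the sum.

Overlapping candidates (≥ 1 shared pixel; a minimum-overlap fraction is
configurable for noisy masks) form buckets as connected components of the
overlap graph.  Within each bucket, selection repeatedly takes the
highest-scoring remaining candidate and discards everything overlapping
it; ties break by larger region, then smaller id — fully deterministic.
Greedy totals never exceed the exhaustive subset optimum and match it on
the overwhelming majority of real buckets (validated against a brute-force
enumeration oracle on buckets of ≤ 10 candidates).  Detection quality is
scored as IoU-matched one-to-one precision/recall/F1 at threshold 0.5.
2-D is fully supported; all operations accept 3-D masks with
26-connectivity.

## Synthetic data

All generators are pure functions of (parameters, seed).

* `gaussian_mixture` — K unit-covariance 2-D normals centered at (i·r, 0):
  the standard spacing-controlled benchmark for cluster-number methods.
* `bitflip_string_set` — the n single-bit-flips of one template; under an
  equal-complexity oracle every partition has zero bandwidth, giving the
  flat-zero structure function used as an analytic fixture.
* `template_class_strings` — each class is a seeded random template over
  its own byte alphabet (alphabet sizes log-spaced 4..256 across classes),
  and each object resamples template bytes within the class alphabet at
  the noise rate.  The distinct alphabet entropies give classes distinct
  per-object compressed sizes — the feature of real image classes (e.g.
  handwritten digits of different complexity) that bandwidth criteria
  respond to.  Uniform full-entropy templates would make every object
  compress to the same size and leave the pipeline structurally blind.
* `cell_image` — bright filled ellipses (pronounced eccentricity, axis
  ratios ≈ 0.6–0.85 vs 1.15–1.55) on a dark noisy background, placed
  without overlap by bounded rejection sampling; ground-truth label masks
  plus candidate masks per radius parameter.  Candidates share one
  Otsu-thresholded foreground; the radius controls the watershed seeding
  distance (≈ 1.6·radius) and a minimal-area filter, so small radii split
  elongated nuclei (over-segmentation) and large radii leave near-lying
  nuclei merged — emulating a single-parameter segmenter swept across
  radii without reimplementing one.

What the generators do *not* emulate: real image textures and codecs'
response to them (the string classes differ in alphabet entropy, not in
visual structure), uneven illumination, out-of-focus light, touching
nuclei with shared boundaries, and anisotropic 3-D stacks.  Passing tests
demonstrate the machinery and its internal consistency on data with a
planted, compressibility- or geometry-expressed cluster structure; they do
not certify accuracy on any particular real dataset.

## Problem sizes and numerical choices

Default desk-scale sizes keep every pipeline in seconds-to-minutes on one
CPU: exact enumeration at n ≤ 8 in tests (guard at 12), string sets of
100 × 1 kB objects with 200 subsamples, Gaussian benchmarks at 500 points
per cluster with 100 seeded trials, cell scenes of 6–8 nuclei at
160–192 px.  Full-scale runs (10⁴ points per cluster, thousands of
subsamples) are configuration changes, not code changes.

Ties and degeneracies: witness partitions take the first minimizer in
enumeration order; mode-label ties in cluster evaluation go to the
smallest class label; identical distances in spectral clustering fall back
to σ = 1 with a single-cluster warning; sigma trimming uses a 1e−12
tolerance so exactly-equal deficiencies always survive; subsample sizes
clamp to |S|.  Seeds propagate from a single root seed through
`numpy.random.default_rng`, and k-means uses a seed derived from it, so
every artifact is reproducible bit-for-bit.

## Known limitations

* The compressed-size proxy is only meaningful when objects are large
  enough that compressor headers do not dominate; self-NCD of a ~1 kB
  object under deflate is ≈ 0.05–0.15, not 0.
* Bandwidth criteria are blind to cluster structure that does not express
  itself in per-object compressed sizes or distances — e.g. classes of
  equal entropy under the chosen compressor.
* On overlapping Gaussian mixtures the Euclidean-deficiency curve is
  smooth, and no selection rule can reliably return the true K once
  components are closer than ≈ 2.5σ: in our experiments at spacing 1.5σ
  even a full Gaussian-mixture BIC (the likelihood-based gold standard)
  prefers 2 components over the true 3 regardless of sample size, and the
  CSF rules select 1–2 as well.  From spacing ≈ 2.5σ the log-ratio rule
  recovers the true K in the large majority of seeded trials.  The
  boundary is a property of the data, not of the estimator.
* The greedy bucket maximizer is not optimal for adversarial score
  configurations (it matches the exhaustive optimum on ≈ 88 % of random
  rectangle/score instances, and on essentially all real ensemble
  buckets).
* `e_background` is unbounded and intensive (a mean ratio), so its scale —
  and thus its weight inside the three-term sum — depends on the adaptive
  threshold offset; the default balances the terms for [0, 1] fluorescent
  -like images but is a knob, not a law.
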