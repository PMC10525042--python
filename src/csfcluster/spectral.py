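"""NCD distance matrices, spectral clustering, and mode-label scoring.

The clustering substrate of the practical pipeline: objects are compared by
normalized compression distance, and the resulting symmetric matrix is
clustered with the classic normalized-cuts spectral recipe — Gaussian
affinity with a median-distance bandwidth, symmetric-normalized Laplacian,
top-k eigenvectors with unit row normalization, then seeded k-means.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .compress import Compressor, CompressorSpec
from .core import CSFError, DataError, ObjectSet, as_object_list

__all__ = ["DistanceMatrix", "ncd_matrix", "spectral_cluster",
           "mode_label_accuracy"]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise DataError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise DataError("ids length must match matrix size")
        if not np.all(np.isfinite(v)):
            raise DataError("non-finite distance entries")
        v = 0.5 * (v + v.T)  # enforce exact symmetry
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


def ncd_matrix(S: ObjectSet | Sequence, spec: CompressorSpec | None = None
               ) -> DistanceMatrix:
    """Pairwise symmetrized NCD among all objects; diagonal forced to 0.

    Uses |S|(|S|-1)/2 pairwise concatenation compressions (both orders per
    pair) plus |S| singleton compressions, all cached within the call.
    """
    objects = as_object_list(S)
    ids = S.ids if isinstance(S, ObjectSet) else [f"obj{i:04d}"
                                                 for i in range(len(objects))]
    n = len(objects)
    if n < 2:
        raise DataError("NCD matrix needs at least two objects")
    comp = Compressor(spec)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                D[i, j] = D[j, i] = comp.ncd(objects[i], objects[j])
            except CSFError as e:
                raise DataError(
                    f"compression failed for pair ({ids[i]}, {ids[j]}): {e}"
                ) from e
    return DistanceMatrix(list(ids), D)


def spectral_cluster(D: DistanceMatrix | np.ndarray, k: int,
                     seed: int | None = None, sigma: float | None = None,
                     n_init: int = 10) -> np.ndarray:
    """Classic spectral clustering of a distance matrix into k groups.

    Affinity A_ij = exp(-D_ij^2 / (2 sigma^2)) with sigma the median
    off-diagonal distance unless given; rows of the top-k eigenvector matrix
    of the symmetric-normalized affinity are unit-normalized and clustered
    with seeded k-means (best of ``n_init`` restarts).  Labels are 0..k-1
    and every label occurs.
    """
    from scipy.linalg import eigh
    from sklearn.cluster import KMeans

    vals = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, float)
    n = vals.shape[0]
    if k > n:
        raise DataError(f"k={k} exceeds number of objects {n}")
    if k == 1:
        return np.zeros(n, dtype=int)

    off = vals[~np.eye(n, dtype=bool)]
    if sigma is None:
        sigma = float(np.median(off))
    if sigma <= 0:
        if np.allclose(off, off.flat[0]):
            warnings.warn("degenerate affinity (all distances identical); "
                          "returning a single cluster", stacklevel=2)
        sigma = 1.0
    A = np.exp(-(vals ** 2) / (2.0 * sigma ** 2))
    np.fill_diagonal(A, 0.0)

    deg = A.sum(axis=1)
    deg[deg <= 0] = 1e-12
    d_isqrt = 1.0 / np.sqrt(deg)
    M = A * d_isqrt[:, None] * d_isqrt[None, :]
    # top-k eigenvectors of the normalized affinity == bottom-k of the
    # symmetric-normalized Laplacian I - M
    _, vecs = eigh(M, subset_by_index=(n - k, n - 1))
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = vecs / norms

    km = KMeans(n_clusters=k, n_init=n_init,
                random_state=None if seed is None else int(seed) % (2**31))
    return km.fit_predict(U)


def mode_label_accuracy(labels: Sequence[int], truth: Sequence
                        ) -> tuple[float, np.ndarray, list]:
    """Score a clustering by mapping each cluster to its modal true label.

    Each cluster is assigned the most common true label among its members
    (ties broken toward the smallest class label); accuracy is the fraction
    of objects whose mapped label matches their true label.  Returns
    (accuracy, confusion matrix with truth rows / predicted columns, the
    sorted class labels indexing both axes).
    """
    labels = np.asarray(labels)
    truth = np.asarray(truth)
    if labels.shape != truth.shape:
        raise DataError("labels and truth must have equal length")
    classes = sorted(set(truth.tolist()))
    class_idx = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    correct = 0
    for c in np.unique(labels):
        members = truth[labels == c]
        uniq, counts = np.unique(members, return_counts=True)
        order = np.lexsort((uniq, -counts))  # max count, then smallest label
        mapped = uniq[order[0]]
        correct += int(counts[order[0]])
        for t, cnt in zip(uniq, counts):
            confusion[class_idx[t], class_idx[mapped]] += int(cnt)
    return correct / len(labels), confusion, classes
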