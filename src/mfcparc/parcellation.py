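"""Clustering seed vertices into sub-regions by connectivity profile.

Two algorithms, as is conventional in connectivity-based parcellation:

* **Spectral** — Ng–Jordan–Weiss normalised spectral clustering on an
  affinity built from pairwise correlations between the rows of the seed
  correlation matrix, remapped to [0, 1] via ``(r + 1) / 2``.
* **Ward** — agglomerative minimum-variance clustering directly on the raw
  Ns x Nw rows with Euclidean distance; no dimensionality reduction.

Cluster ids are relabelled canonically by order of first appearance along
the seed-vertex ordering, so outputs are stable files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .connectivity import SeedCorrelationMatrix
from .exceptions import DegenerateInputError, InputError, NumericalError

__all__ = [
    "AffinityMatrix",
    "Parcellation",
    "build_affinity",
    "spectral_parcellate",
    "ward_parcellate",
    "ward_linkage",
]


@dataclass
class AffinityMatrix:
    """Symmetric Ns x Ns similarity in [0, 1] with unit diagonal."""

    a: np.ndarray
    seed_vertex_ids: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.seed_vertex_ids = np.asarray(self.seed_vertex_ids)
        n = self.a.shape[0]
        if self.a.shape != (n, n) or n != len(self.seed_vertex_ids):
            raise InputError("affinity must be square and match seed ids")
        if np.abs(self.a - self.a.T).max() > 1e-10:
            raise InputError("affinity must be symmetric")
        if self.a.min() < -1e-12 or self.a.max() > 1 + 1e-12:
            raise InputError("affinity entries must lie in [0, 1]")


@dataclass
class Parcellation:
    """Seed-vertex -> cluster-label assignment (labels 1..k, all nonempty)."""

    labels: np.ndarray
    k: int
    algorithm: str
    seed_vertex_ids: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.seed_vertex_ids = np.asarray(self.seed_vertex_ids)
        if len(self.labels) != len(self.seed_vertex_ids):
            raise InputError("labels and seed ids differ in length")
        present = np.unique(self.labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise InputError(
                f"labels must cover 1..k={self.k} with no empty cluster"
            )

    def cluster_vertices(self, label: int) -> np.ndarray:
        """Seed vertex ids belonging to one cluster."""
        return self.seed_vertex_ids[self.labels == label]

    @property
    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k + 1)[1:]


def canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k by order of first appearance."""
    raw = np.asarray(raw)
    mapping: dict = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def build_affinity(m: SeedCorrelationMatrix) -> AffinityMatrix:
    """Pairwise row correlations of the connectivity matrix, mapped to [0, 1].

    ``a[i, j] = (corr(row_i, row_j) + 1) / 2`` with the diagonal set to 1
    exactly. Rows are the stored Fisher-z profiles.
    """
    if m.n_seed < 2 or m.n_target < 3:
        raise InputError("affinity needs Ns >= 2 and Nw >= 3")
    centered = m.z - m.z.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise DegenerateInputError(
            f"zero-variance connectivity row for seed vertex id(s) "
            f"{np.asarray(m.seed_vertex_ids)[bad].tolist()}"
        )
    r = np.clip((centered / norms[:, None]) @ (centered / norms[:, None]).T, -1, 1)
    a = (r + 1.0) / 2.0
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return AffinityMatrix(a=a, seed_vertex_ids=m.seed_vertex_ids)


def spectral_parcellate(
    a: AffinityMatrix, k: int, rng_seed: int = 0, n_restarts: int = 50
) -> Parcellation:
    """Normalised spectral clustering of the affinity into k clusters.

    The k leading eigenvectors of ``D^{-1/2} A D^{-1/2}`` form the
    embedding; rows are normalised to the unit sphere and partitioned with
    seeded k-means (best of ``n_restarts`` initialisations). Eigenvectors
    are sorted by descending eigenvalue and sign-fixed (first nonzero
    coordinate positive) so the embedding, and hence the run, is
    deterministic given ``rng_seed``.
    """
    n = a.a.shape[0]
    if not 2 <= k <= n:
        raise InputError(f"k must lie in [2, {n}], got {k}")
    d = a.a.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    m = inv_sqrt[:, None] * a.a * inv_sqrt[None, :]
    try:
        vals, vecs = scipy.linalg.eigh(m, subset_by_index=(n - k, n - 1))
    except scipy.linalg.LinAlgError as exc:  # pragma: no cover
        raise NumericalError(f"eigendecomposition failed: {exc}") from exc
    order = np.argsort(vals)[::-1]
    vecs = vecs[:, order]
    for j in range(k):
        col = vecs[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            vecs[:, j] = -col
    norms = np.linalg.norm(vecs, axis=1, keepdims=True)
    emb = np.divide(vecs, norms, out=vecs.copy(), where=norms > 0)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=rng_seed)
    raw = km.fit_predict(emb)
    if len(np.unique(raw)) != k:  # pragma: no cover - kmeans keeps k nonempty
        raise NumericalError("spectral embedding collapsed below k clusters")
    return Parcellation(
        labels=canonical_labels(raw),
        k=k,
        algorithm="spectral",
        seed_vertex_ids=a.seed_vertex_ids,
    )


def ward_linkage(m: SeedCorrelationMatrix) -> np.ndarray:
    """Ward minimum-variance linkage of the raw connectivity rows."""
    return linkage(m.z, method="ward")


def ward_parcellate(m: SeedCorrelationMatrix, k: int) -> Parcellation:
    """Agglomerative Ward clustering of the Ns x Nw rows, cut at k clusters.

    Euclidean distances on the raw Fisher-z profiles; fully deterministic.
    """
    n = m.n_seed
    if not 2 <= k <= n:
        raise InputError(f"k must lie in [2, {n}], got {k}")
    raw = fcluster(ward_linkage(m), t=k, criterion="maxclust")
    if len(np.unique(raw)) != k:
        raise NumericalError(
            f"Ward cut produced {len(np.unique(raw))} clusters instead of {k} "
            "(tied merge heights)"
        )
    return Parcellation(
        labels=canonical_labels(raw),
        k=k,
        algorithm="ward",
        seed_vertex_ids=m.seed_vertex_ids,
    )
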