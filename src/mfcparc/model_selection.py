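"""Choosing the number of clusters.

Two complementary criteria:

* **Split-half variation of information (VI).** Subjects are repeatedly
  split into two halves; each half is aggregated and parcellated at each k
  and the two partitions are compared with VI. Low average VI means the
  parcellation is reproducible at that k.
* **Per-subject silhouette.** Each subject's own connectivity matrix is
  parcellated at each k and the mean silhouette width of the labels
  (Euclidean distance between connectivity rows) is averaged over subjects.
  The silhouette argmax is the selected k; ties go to the smallest k, the
  model with the fewest degrees of freedom.

The VI curve additionally yields a "plateau" candidate: scanning from the
largest k downward, the first k whose VI is not significantly different
from the VI at k-1 (paired t-test across the split-half repeats). With
real structure VI typically keeps increasing significantly with k and no
plateau exists; the silhouette argmax then decides alone.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import ttest_rel

from .connectivity import (
    SeedCorrelationMatrix,
    ThicknessStack,
    group_sum,
    seed_correlation_thickness,
)
from .exceptions import InputError
from .parcellation import Parcellation, build_affinity, spectral_parcellate, ward_parcellate

__all__ = [
    "VICurve",
    "SilhouetteCurve",
    "KSelection",
    "variation_of_information",
    "split_half_vi",
    "silhouette_curve",
    "mean_silhouette",
    "select_k",
]


def variation_of_information(p: Parcellation, q: Parcellation) -> float:
    """VI(p, q) = H(p) + H(q) - 2 I(p, q), in nats.

    Computed from the joint label-contingency table. Symmetric,
    nonnegative, zero iff the partitions agree up to relabelling, and
    bounded by ln(n).
    """
    if not np.array_equal(p.seed_vertex_ids, q.seed_vertex_ids):
        raise InputError("partitions are over different seed vertex sets")
    n = len(p.labels)
    cont = np.zeros((p.k, q.k))
    np.add.at(cont, (p.labels - 1, q.labels - 1), 1.0)
    pij = cont / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h1 = -np.sum(pi[pi > 0] * np.log(pi[pi > 0]))
        h2 = -np.sum(pj[pj > 0] * np.log(pj[pj > 0]))
        nz = pij > 0
        mi = np.sum(pij[nz] * np.log(pij[nz] / np.outer(pi, pj)[nz]))
    vi = h1 + h2 - 2 * mi
    return 0.0 if vi < 1e-12 else float(vi)  # clamp rounding residue at 0


@dataclass
class VICurve:
    k_values: List[int]
    vi_samples: List[np.ndarray]  # one array of length n_repeats per k
    n_repeats: int

    @property
    def mean_vi(self) -> np.ndarray:
        return np.array([s.mean() for s in self.vi_samples])

    def plot(self, ax=None):
        """VI versus k (mean over split-half repeats)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.k_values, self.mean_vi, marker="o")
        ax.set_xlabel("number of clusters k")
        ax.set_ylabel("mean split-half VI (nats)")
        return ax


@dataclass
class SilhouetteCurve:
    k_values: List[int]
    per_subject_values: List[np.ndarray]  # one array of length n_subjects per k

    @property
    def mean_silhouette(self) -> np.ndarray:
        return np.array([s.mean() for s in self.per_subject_values])

    def plot(self, ax=None):
        """Mean silhouette versus k."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.k_values, self.mean_silhouette, marker="o")
        ax.set_xlabel("number of clusters k")
        ax.set_ylabel("mean silhouette")
        return ax


@dataclass
class KSelection:
    """Outcome of model selection over a k range."""

    k: int  # the silhouette argmax (smallest k on exact ties)
    vi_plateau_k: int | None  # None when VI never plateaus
    disagree: bool


def _parcellate(m: SeedCorrelationMatrix, k: int, algorithm: str, rng_seed: int):
    if algorithm == "ward":
        return ward_parcellate(m, k)
    if algorithm == "spectral":
        return spectral_parcellate(build_affinity(m), k, rng_seed=rng_seed)
    raise InputError(f"unknown algorithm {algorithm!r}")


def _half_aggregate(units, idx, seed_ids, target_ids):
    if isinstance(units, ThicknessStack):
        return seed_correlation_thickness(
            ThicknessStack(units.data[idx]), seed_ids, target_ids
        )
    return group_sum([units[i] for i in idx])


def split_half_vi(
    units,
    k_values: Sequence[int],
    algorithm: str = "ward",
    n_repeats: int = 100,
    rng_seed: int = 0,
    seed_ids=None,
    target_ids=None,
) -> VICurve:
    """Split-half reproducibility of the parcellation, per k.

    ``units`` is either a list of per-subject functional
    :class:`SeedCorrelationMatrix` (aggregated per half by summation) or a
    :class:`ThicknessStack` (each half's matrix computed from that half's
    subjects; ``seed_ids``/``target_ids`` then required). Halves are
    disjoint and differ in size by at most one subject.
    """
    if isinstance(units, ThicknessStack):
        n_units = units.n_subjects
        if seed_ids is None or target_ids is None:
            raise InputError("thickness mode needs seed_ids and target_ids")
    else:
        units = list(units)
        n_units = len(units)
    if n_units < 4:
        raise InputError("need at least 4 units for a split-half comparison")
    k_values = list(k_values)
    rng = np.random.default_rng(rng_seed)
    samples = {k: [] for k in k_values}
    for rep in range(n_repeats):
        perm = rng.permutation(n_units)
        half1, half2 = perm[: n_units // 2], perm[n_units // 2:]
        sub_seed = int(rng.integers(2**31))
        try:
            m1 = _half_aggregate(units, half1, seed_ids, target_ids)
            m2 = _half_aggregate(units, half2, seed_ids, target_ids)
            for k in k_values:
                p1 = _parcellate(m1, k, algorithm, sub_seed)
                p2 = _parcellate(m2, k, algorithm, sub_seed)
                samples[k].append(variation_of_information(p1, p2))
        except Exception as exc:
            raise type(exc)(f"split-half repeat {rep}: {exc}") from exc
    return VICurve(
        k_values=k_values,
        vi_samples=[np.array(samples[k]) for k in k_values],
        n_repeats=n_repeats,
    )


def mean_silhouette(x: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width of a labelling of the rows of ``x``.

    Euclidean distances; a point in a singleton cluster contributes 0.
    Defined for any number of clusters including all-singletons.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise InputError("silhouette needs at least 2 clusters")
    d = squareform(pdist(np.asarray(x, dtype=float)))
    n = len(labels)
    s = np.zeros(n)
    members = {lab: np.flatnonzero(labels == lab) for lab in uniq}
    for i in range(n):
        own = members[labels[i]]
        if own.size == 1:
            continue  # singleton convention: s = 0
        a = d[i, own].sum() / (own.size - 1)
        b = min(d[i, members[lab]].mean() for lab in uniq if lab != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def silhouette_curve(
    subject_matrices: Sequence[SeedCorrelationMatrix],
    k_values: Sequence[int],
    algorithm: str = "ward",
    rng_seed: int = 0,
) -> SilhouetteCurve:
    """Per-subject parcellation quality across k.

    Each subject's own connectivity matrix is parcellated at every k and
    scored by the mean silhouette of its labels over the Euclidean
    geometry of its connectivity rows.
    """
    k_values = list(k_values)
    per_k = {k: [] for k in k_values}
    for m in subject_matrices:
        for k in k_values:
            p = _parcellate(m, k, algorithm, rng_seed)
            per_k[k].append(mean_silhouette(m.z, p.labels))
    return SilhouetteCurve(
        k_values=k_values,
        per_subject_values=[np.array(per_k[k]) for k in k_values],
    )


def select_k(vi: VICurve, sil: SilhouetteCurve, alpha: float = 0.05) -> KSelection:
    """Pick k: silhouette argmax, with the VI plateau as a cross-check.

    Smallest k wins exact silhouette ties. The plateau candidate is the
    smallest k whose VI does not differ significantly from the VI at k-1
    (paired two-sided t-test across repeats at level ``alpha``); ``None``
    when every adjacent step is significant, in which case the curves are
    flagged as disagreeing only if a plateau exists and differs from the
    silhouette argmax.
    """
    if not vi.k_values or not sil.k_values:
        raise InputError("empty model-selection curves")
    if list(vi.k_values) != list(sil.k_values):
        raise InputError("VI and silhouette curves cover different k values")
    means = sil.mean_silhouette
    k_sil = sil.k_values[int(np.argmax(means))]  # argmax -> first -> smallest k

    plateau = None
    for i in range(len(vi.k_values) - 1, 0, -1):
        a, b = vi.vi_samples[i], vi.vi_samples[i - 1]
        diffs = a - b
        if np.allclose(diffs, diffs[0]):
            significant = False  # no variability across repeats: no evidence
        else:
            significant = ttest_rel(a, b).pvalue < alpha
        if not significant:
            plateau = vi.k_values[i]
    return KSelection(
        k=k_sil,
        vi_plateau_k=plateau,
        disagree=plateau is not None and plateau != k_sil,
    )
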