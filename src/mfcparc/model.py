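"""Model / Results interface over the parcellation machinery.

:class:`ParcellationModel` is built from data (a group seed-correlation
matrix, optionally with the per-subject matrices it was aggregated from);
``fit(k)`` returns a :class:`ParcellationResults` carrying the labels and
fit diagnostics, with ``summary()``, cross-parcellation comparison and
model-selection helpers hanging off the two objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .comparison import DiceReport, atlas_overlap, dice_overlap
from .connectivity import (
    SeedCorrelationMatrix,
    group_sum,
    seed_correlation_fmri,
    seed_correlation_thickness,
)
from .exceptions import InputError
from .model_selection import (
    KSelection,
    SilhouetteCurve,
    VICurve,
    mean_silhouette,
    select_k,
    silhouette_curve,
    split_half_vi,
)
from .parcellation import (
    Parcellation,
    build_affinity,
    spectral_parcellate,
    ward_parcellate,
)

__all__ = ["ParcellationModel", "ParcellationResults"]


class ParcellationModel:
    """Connectivity-based parcellation of a seed region.

    Parameters
    ----------
    matrix
        The group-level Ns x Nw Fisher-z seed correlation matrix.
    subject_matrices
        Optional per-subject matrices (functional modality); required for
        split-half and per-subject model-selection diagnostics.
    algorithm
        ``"ward"`` (agglomerative minimum-variance on raw rows, the
        default) or ``"spectral"`` (normalised spectral clustering of the
        row-correlation affinity).

    Examples
    --------
    >>> from mfcparc import CohortConfig, generate_cohort, ParcellationModel
    >>> cohort = generate_cohort(CohortConfig(rng_seed=7))
    >>> model = ParcellationModel.from_cohort(cohort, modality="fmri")
    >>> res = model.fit(k=2)
    >>> res.labels[:5]
    array([1, 1, 1, 1, 1])
    """

    def __init__(
        self,
        matrix: SeedCorrelationMatrix,
        subject_matrices: Optional[Sequence[SeedCorrelationMatrix]] = None,
        algorithm: str = "ward",
    ):
        if algorithm not in ("ward", "spectral"):
            raise InputError(f"unknown algorithm {algorithm!r}")
        self.matrix = matrix
        self.subject_matrices = (
            list(subject_matrices) if subject_matrices is not None else None
        )
        self.algorithm = algorithm

    @classmethod
    def from_cohort(
        cls, cohort, modality: str = "fmri", algorithm: str = "ward",
        seed_ids=None, target_ids=None,
    ) -> "ParcellationModel":
        """Build the model from a (synthetic or loaded) cohort.

        Functional mode sums the per-subject matrices; thickness mode uses
        the single group-level structural-covariance matrix.
        """
        seed_ids = cohort.seed_vertex_ids if seed_ids is None else seed_ids
        target_ids = cohort.target_vertex_ids if target_ids is None else target_ids
        if modality == "fmri":
            per = [
                seed_correlation_fmri(ts, seed_ids, target_ids)
                for ts in cohort.timeseries
            ]
            return cls(group_sum(per), subject_matrices=per, algorithm=algorithm)
        if modality == "thickness":
            m = seed_correlation_thickness(cohort.thickness, seed_ids, target_ids)
            return cls(m, algorithm=algorithm)
        raise InputError(f"unknown modality {modality!r}")

    def fit(self, k: int = 2, rng_seed: int = 0) -> "ParcellationResults":
        """Parcellate into k clusters and return the results object."""
        if self.algorithm == "ward":
            p = ward_parcellate(self.matrix, k)
        else:
            p = spectral_parcellate(build_affinity(self.matrix), k, rng_seed=rng_seed)
        sil = mean_silhouette(self.matrix.z, p.labels)
        return ParcellationResults(model=self, parcellation=p, silhouette=sil)

    def select_k(
        self,
        k_values: Sequence[int] = range(2, 11),
        n_repeats: int = 100,
        rng_seed: int = 0,
        alpha: float = 0.05,
    ) -> tuple[KSelection, VICurve, SilhouetteCurve]:
        """Split-half VI and per-subject silhouette over a k range.

        Requires per-subject matrices.
        """
        if not self.subject_matrices:
            raise InputError("select_k requires per-subject matrices")
        vi = split_half_vi(
            self.subject_matrices, k_values, algorithm=self.algorithm,
            n_repeats=n_repeats, rng_seed=rng_seed,
        )
        sil = silhouette_curve(
            self.subject_matrices, k_values, algorithm=self.algorithm,
            rng_seed=rng_seed,
        )
        return select_k(vi, sil, alpha=alpha), vi, sil


@dataclass
class ParcellationResults:
    """Fitted parcellation: labels, diagnostics, comparisons."""

    model: ParcellationModel = field(repr=False)
    parcellation: Parcellation
    silhouette: float

    @property
    def labels(self) -> np.ndarray:
        return self.parcellation.labels

    @property
    def k(self) -> int:
        return self.parcellation.k

    @property
    def cluster_sizes(self) -> np.ndarray:
        return self.parcellation.cluster_sizes

    def compare(self, other: "ParcellationResults | Parcellation") -> DiceReport:
        """Matched dice agreement with another parcellation of the same
        seed set (cross-modal or cross-algorithm)."""
        q = other.parcellation if isinstance(other, ParcellationResults) else other
        return dice_overlap(self.parcellation, q)

    def atlas_overlap(self, region_mask: np.ndarray):
        """Per-cluster fraction inside an external region mask."""
        return atlas_overlap(self.parcellation, region_mask)

    def summary(self) -> str:
        p = self.parcellation
        m = self.model.matrix
        sizes = ", ".join(
            f"{lab}: {n}" for lab, n in zip(range(1, p.k + 1), p.cluster_sizes)
        )
        lines = [
            "Connectivity-based parcellation",
            "=" * 48,
            f"modality:         {m.modality}",
            f"algorithm:        {p.algorithm}",
            f"seed vertices:    {m.n_seed}",
            f"target vertices:  {m.n_target}",
            f"subjects:         {m.n_aggregated}",
            f"clusters (k):     {p.k}",
            f"cluster sizes:    {sizes}",
            f"mean silhouette:  {self.silhouette:.4f}",
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Cluster assignment along the seed-vertex ordering."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 1.8))
        ax.scatter(
            self.parcellation.seed_vertex_ids, self.labels,
            c=self.labels, cmap="tab10", s=12,
        )
        ax.set_xlabel("seed vertex id")
        ax.set_ylabel("cluster")
        ax.set_yticks(range(1, self.k + 1))
        return ax
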