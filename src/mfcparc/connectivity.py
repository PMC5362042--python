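"""Seed-to-brain correlation matrices from two imaging modalities.

Functional connectivity correlates vertex time series within a subject;
structural covariance correlates cortical thickness across subjects. Both
produce an ``Ns x Nw`` matrix of Fisher-z transformed Pearson correlations
between each seed vertex and each target (non-seed cerebral) vertex. The
functional matrices are summed over subjects to represent a group; the
thickness matrix is a single group-level object by construction.

Inter-subject reliability is quantified by k-fold resampling: the aggregate
connectivity profile of held-in subjects is correlated, per seed vertex,
against the held-out aggregate, and averaged over folds and repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import DegenerateInputError, InputError

__all__ = [
    "FISHER_CLIP",
    "SubjectTimeSeries",
    "ThicknessStack",
    "SeedCorrelationMatrix",
    "StabilityMap",
    "fisher_z",
    "seed_correlation_fmri",
    "seed_correlation_thickness",
    "group_sum",
    "stability_map_fmri",
    "stability_map_thickness",
]

#: correlations are clipped to +/- (1 - 1e-7) before arctanh so that exact
#: r = +/-1 (duplicated vertices, noiseless synthetic data) stays finite
FISHER_CLIP = 1.0 - 1e-7


@dataclass
class SubjectTimeSeries:
    """One subject's processed signal matrix, vertices x timepoints."""

    data: np.ndarray
    subject_id: str = "subject"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InputError("time-series data must be 2-D (vertices x timepoints)")
        if self.data.shape[1] < 4:
            raise InputError(
                f"need >= 4 timepoints, got {self.data.shape[1]} "
                f"for subject {self.subject_id!r}"
            )

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


@dataclass
class ThicknessStack:
    """Registered cortical thickness, subjects x vertices (mm).

    The cross-subject vector at one vertex plays the role the time series
    plays in the functional modality: its length is the number of subjects
    being modelled.
    """

    data: np.ndarray
    subject_ids: Sequence[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InputError("thickness data must be 2-D (subjects x vertices)")
        if self.data.shape[0] < 4:
            raise InputError(f"need >= 4 subjects, got {self.data.shape[0]}")
        if not np.all(np.isfinite(self.data)) or np.any(self.data <= 0):
            raise InputError("thickness values must be finite and > 0")
        if self.subject_ids is None:
            self.subject_ids = [f"sub-{i:03d}" for i in range(self.data.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.data.shape[1]


@dataclass
class SeedCorrelationMatrix:
    """Ns x Nw Fisher-z connectivity matrix from one modality.

    ``n_aggregated`` counts subjects summed into the matrix (functional
    mode) or the subjects entering the single cross-subject correlation
    (thickness mode).
    """

    z: np.ndarray
    seed_vertex_ids: np.ndarray
    target_vertex_ids: np.ndarray
    modality: str
    n_aggregated: int = 1

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.seed_vertex_ids = np.asarray(self.seed_vertex_ids)
        self.target_vertex_ids = np.asarray(self.target_vertex_ids)
        if self.modality not in ("fmri", "thickness"):
            raise InputError(f"unknown modality {self.modality!r}")
        if self.z.shape != (len(self.seed_vertex_ids), len(self.target_vertex_ids)):
            raise InputError("z shape does not match seed/target id counts")
        if np.intersect1d(self.seed_vertex_ids, self.target_vertex_ids).size:
            raise InputError("seed and target vertex id sets must be disjoint")
        if not np.all(np.isfinite(self.z)):
            raise InputError("non-finite values in correlation matrix")

    @property
    def n_seed(self) -> int:
        return self.z.shape[0]

    @property
    def n_target(self) -> int:
        return self.z.shape[1]


@dataclass
class StabilityMap:
    """Per-seed-vertex inter-subject reliability of the connectivity profile."""

    mean_r: np.ndarray
    n_folds: int
    n_repeats: int

    def __post_init__(self) -> None:
        self.mean_r = np.asarray(self.mean_r, dtype=float)
        if np.any(np.abs(self.mean_r) > 1 + 1e-12):
            raise InputError("stability values must lie in [-1, 1]")

    @property
    def mean(self) -> float:
        """Vertex-average stability (the single summary number)."""
        return float(self.mean_r.mean())


def fisher_z(r):
    """Fisher r-to-z transform, arctanh(r), with clipping at |r| = 1.

    Accepts scalars or arrays. Values with |r| > 1 beyond numerical
    tolerance raise; |r| within [1, 1 + tol] (and exact +/-1) are clipped
    to ``FISHER_CLIP`` so the transform stays finite.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1 + 1e-8):
        raise InputError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(arr, -FISHER_CLIP, FISHER_CLIP))
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def _standardize_rows(x: np.ndarray, what: str, ids) -> np.ndarray:
    """Center and scale rows to unit norm; zero-variance rows are errors."""
    mu = x.mean(axis=1, keepdims=True)
    centered = x - mu
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    bad = np.flatnonzero(norms.ravel() == 0)
    if bad.size:
        raise DegenerateInputError(
            f"zero-variance {what} at vertex id(s) {np.asarray(ids)[bad].tolist()}"
        )
    return centered / norms


def _check_ids(n_vertices: int, seed_ids, target_ids):
    seed_ids = np.asarray(seed_ids, dtype=int)
    target_ids = np.asarray(target_ids, dtype=int)
    for name, ids in (("seed", seed_ids), ("target", target_ids)):
        if ids.size == 0:
            raise InputError(f"empty {name} vertex id list")
        if ids.min() < 0 or ids.max() >= n_vertices:
            raise InputError(f"{name} vertex ids out of range [0, {n_vertices})")
    if np.intersect1d(seed_ids, target_ids).size:
        raise InputError("seed and target vertex ids overlap")
    return seed_ids, target_ids


def seed_correlation_fmri(
    ts: SubjectTimeSeries, seed_ids, target_ids
) -> SeedCorrelationMatrix:
    """One subject's Ns x Nw Fisher-z functional connectivity matrix.

    Each row is the Pearson correlation of one seed vertex's time series
    with every target vertex's time series, r-to-z transformed.
    """
    seed_ids, target_ids = _check_ids(ts.n_vertices, seed_ids, target_ids)
    zs = _standardize_rows(ts.data[seed_ids], "time series", seed_ids)
    zt = _standardize_rows(ts.data[target_ids], "time series", target_ids)
    r = np.clip(zs @ zt.T, -1.0, 1.0)
    return SeedCorrelationMatrix(
        z=fisher_z(r),
        seed_vertex_ids=seed_ids,
        target_vertex_ids=target_ids,
        modality="fmri",
        n_aggregated=1,
    )


def seed_correlation_thickness(
    stack: ThicknessStack, seed_ids, target_ids
) -> SeedCorrelationMatrix:
    """Group-level Ns x Nw Fisher-z structural-covariance matrix.

    Correlations are taken across subjects between thickness at a seed
    vertex and thickness at each target vertex.
    """
    seed_ids, target_ids = _check_ids(stack.n_vertices, seed_ids, target_ids)
    zs = _standardize_rows(stack.data[:, seed_ids].T, "thickness", seed_ids)
    zt = _standardize_rows(stack.data[:, target_ids].T, "thickness", target_ids)
    r = np.clip(zs @ zt.T, -1.0, 1.0)
    return SeedCorrelationMatrix(
        z=fisher_z(r),
        seed_vertex_ids=seed_ids,
        target_vertex_ids=target_ids,
        modality="thickness",
        n_aggregated=stack.n_subjects,
    )


def group_sum(matrices: Sequence[SeedCorrelationMatrix]) -> SeedCorrelationMatrix:
    """Elementwise sum of same-shaped matrices: the group representation
    used by the functional modality."""
    if not matrices:
        raise InputError("group_sum requires at least one matrix")
    first = matrices[0]
    total = np.zeros_like(first.z)
    n_agg = 0
    for m in matrices:
        if m.modality != first.modality:
            raise InputError("cannot sum matrices of different modalities")
        if m.z.shape != first.z.shape or not (
            np.array_equal(m.seed_vertex_ids, first.seed_vertex_ids)
            and np.array_equal(m.target_vertex_ids, first.target_vertex_ids)
        ):
            raise InputError("shape or vertex-id mismatch in group_sum")
        total += m.z
        n_agg += m.n_aggregated
    return SeedCorrelationMatrix(
        z=total,
        seed_vertex_ids=first.seed_vertex_ids,
        target_vertex_ids=first.target_vertex_ids,
        modality=first.modality,
        n_aggregated=n_agg,
    )


def _fold_sizes(n: int, n_folds: int) -> list[int]:
    # rounded equal folds with the remainder in the last one
    # (248 subjects over 5 folds -> 50/50/50/50/48)
    base = max(1, round(n / n_folds))
    if base * (n_folds - 1) >= n:  # keep the last fold nonempty
        base = (n - 1) // (n_folds - 1)
    return [base] * (n_folds - 1) + [n - base * (n_folds - 1)]


def _rowwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r between corresponding rows of two equal-shaped matrices."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    num = (ac * bc).sum(axis=1)
    den = np.linalg.norm(ac, axis=1) * np.linalg.norm(bc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.clip(r, -1.0, 1.0)


def _stability_from_fold_aggregates(aggregate, units_idx, n_folds, n_repeats, rng_seed):
    """Shared resampling loop: ``aggregate(indices) -> Ns x Nw array``."""
    n_units = len(units_idx)
    if n_folds < 2 or n_folds > n_units:
        raise InputError(
            f"cannot form {n_folds} nonempty folds from {n_units} units"
        )
    rng = np.random.default_rng(rng_seed)
    sizes = _fold_sizes(n_units, n_folds)
    acc = None
    count = 0
    for _ in range(n_repeats):
        perm = rng.permutation(n_units)
        bounds = np.cumsum([0] + sizes)
        folds = [perm[bounds[i]:bounds[i + 1]] for i in range(n_folds)]
        for i in range(n_folds):
            held_out = aggregate(folds[i])
            held_in = aggregate(np.concatenate(folds[:i] + folds[i + 1:]))
            r = _rowwise_corr(held_in, held_out)
            acc = r if acc is None else acc + r
            count += 1
    return StabilityMap(mean_r=acc / count, n_folds=n_folds, n_repeats=n_repeats)


def stability_map_fmri(
    matrices: Sequence[SeedCorrelationMatrix],
    n_folds: int = 5,
    n_repeats: int = 30,
    rng_seed: int = 0,
) -> StabilityMap:
    """Inter-subject reliability of the summed functional connectivity.

    Per repeat, subjects are split into ``n_folds`` near-equal groups; for
    each fold the sum of the held-in per-subject matrices is correlated, per
    seed vertex across targets, with the held-out sum.
    """
    stack = np.stack([m.z for m in matrices])

    def aggregate(idx):
        return stack[idx].sum(axis=0)

    return _stability_from_fold_aggregates(
        aggregate, list(range(len(matrices))), n_folds, n_repeats, rng_seed
    )


def stability_map_thickness(
    stack: ThicknessStack,
    seed_ids,
    target_ids,
    n_folds: int = 5,
    n_repeats: int = 30,
    rng_seed: int = 0,
) -> StabilityMap:
    """Inter-subject reliability of structural covariance.

    Thickness has no per-subject matrix: each fold-group of subjects yields
    one correlation matrix from that group's stack, the four held-in group
    matrices are summed, and the sum is compared with the held-out group's
    matrix.
    """
    n_units = stack.n_subjects
    rng = np.random.default_rng(rng_seed)
    sizes = _fold_sizes(n_units, n_folds)
    if n_folds < 2 or n_folds > n_units or min(sizes) < 4:
        raise InputError(
            f"cannot form {n_folds} thickness folds of >= 4 subjects from {n_units}"
        )
    acc = None
    count = 0
    for _ in range(n_repeats):
        perm = rng.permutation(n_units)
        bounds = np.cumsum([0] + sizes)
        folds = [perm[bounds[i]:bounds[i + 1]] for i in range(n_folds)]
        fold_mats = [
            seed_correlation_thickness(
                ThicknessStack(stack.data[f]), seed_ids, target_ids
            ).z
            for f in folds
        ]
        for i in range(n_folds):
            held_out = fold_mats[i]
            held_in = sum(fold_mats[j] for j in range(n_folds) if j != i)
            r = _rowwise_corr(held_in, held_out)
            acc = r if acc is None else acc + r
            count += 1
    return StabilityMap(mean_r=acc / count, n_folds=n_folds, n_repeats=n_repeats)
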