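"""Whole-brain connectivity of a parcellated seed sub-region.

The sub-region is treated as a whole: its spatial average signal is
correlated with the average signal of every atlas region. In the
functional mode this happens per subject, and per-region Fisher-z values
are tested across subjects with a one-sample right-tailed t-test followed
by Benjamini–Hochberg FDR correction over regions. In the thickness mode
a single group-level correlation per region is Fisher-z transformed and
thresholded (z > 0.4 by default); its p-value comes from the large-sample
null z ~ Normal(0, 1/sqrt(n - 3)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DegenerateInputError, InputError

__all__ = [
    "RegionAtlas",
    "SeedNetworkResult",
    "region_average",
    "fmri_seed_network",
    "thickness_seed_network",
    "fdr_bh",
]


@dataclass
class RegionAtlas:
    """Vertex -> anatomical region labelling; 0 means unassigned."""

    region_of: np.ndarray
    region_names: Dict[int, str]

    def __post_init__(self) -> None:
        self.region_of = np.asarray(self.region_of, dtype=int)
        present = set(np.unique(self.region_of)) - {0}
        missing = set(self.region_names) - present
        if missing:
            raise InputError(f"named regions with no vertices: {sorted(missing)}")

    @property
    def region_ids(self) -> list:
        return sorted(set(np.unique(self.region_of)) - {0})

    def name(self, region_id: int) -> str:
        return self.region_names.get(region_id, f"region_{region_id}")

    def vertices(self, region_id: int) -> np.ndarray:
        return np.flatnonzero(self.region_of == region_id)


@dataclass
class SeedNetworkResult:
    """Per-region statistics for one seed sub-region.

    ``table`` has one row per atlas region with columns
    ``region_id, region, statistic, raw_p, corrected_p, significant``.
    In thickness mode the statistic is the group z and ``corrected_p``
    equals ``raw_p`` (significance is the z threshold, not a correction).
    """

    table: pd.DataFrame = field(repr=False)
    mode: str
    n: int  # subjects
    alpha: float | None = None
    z_threshold: float | None = None

    @property
    def significant_regions(self) -> list:
        return self.table.loc[self.table["significant"], "region"].tolist()

    def summary(self) -> str:
        stat = "t" if self.mode == "fmri" else "z"
        lines = [
            f"Seed-network analysis ({self.mode} mode, n = {self.n} subjects)",
            (
                f"significance: BH-FDR corrected p < {self.alpha}"
                if self.mode == "fmri"
                else f"significance: {stat} > {self.z_threshold}"
            ),
            "",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.5f}"),
        ]
        return "\n".join(lines)


def region_average(values: np.ndarray, atlas: RegionAtlas, region_id: int) -> np.ndarray:
    """Unweighted mean of a vertex-indexed array over one region.

    ``values`` has vertices along axis 0 (vertices x timepoints for time
    series, vertices x subjects for a transposed thickness stack, or a
    plain per-vertex vector).
    """
    idx = atlas.vertices(region_id)
    if idx.size == 0:
        raise InputError(f"region {region_id} has no vertices")
    return np.asarray(values, dtype=float)[idx].mean(axis=0)


def fdr_bh(p_values: Sequence[float], alpha: float = 0.05):
    """Benjamini–Hochberg step-up over a family of p-values.

    Returns ``(reject, adjusted_p)`` arrays.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise InputError("empty p-value list")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject, adj


def _mean_over(values: np.ndarray, idx: np.ndarray) -> np.ndarray:
    idx = np.asarray(idx, dtype=int)
    if idx.size == 0:
        raise InputError("empty seed cluster")
    return np.asarray(values, dtype=float)[idx].mean(axis=0)


def _corr(a: np.ndarray, b: np.ndarray, what: str) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.linalg.norm(a) * np.linalg.norm(b)
    if den == 0:
        raise DegenerateInputError(f"zero-variance averaged {what}")
    return float(np.clip(a @ b / den, -1.0, 1.0))


def _one_sample_t_greater(z: np.ndarray):
    """Right-tailed one-sample t against 0; zero-variance samples collapse
    to a sign-determined limit rather than NaN."""
    if np.ptp(z) == 0:
        mean = z[0]
        if mean > 0:
            return np.inf, 0.0
        if mean < 0:
            return -np.inf, 1.0
        return 0.0, 0.5
    res = stats.ttest_1samp(z, 0.0, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def fmri_seed_network(
    subjects,
    atlas: RegionAtlas,
    seed_cluster_vertices,
    alpha: float = 0.05,
) -> SeedNetworkResult:
    """Functional whole-brain connectivity of one seed sub-region.

    Per subject, the seed cluster's average time series is correlated with
    each atlas region's average series and Fisher-z transformed; per
    region, the z values are tested across subjects (one-sample,
    right-tailed) and BH-FDR corrected over regions.
    """
    from .connectivity import fisher_z  # local to avoid import cycle at module load

    subjects = list(subjects)
    if len(subjects) < 4:
        raise InputError("need at least 4 subjects")
    region_ids = atlas.region_ids
    if not region_ids:
        raise InputError("atlas names no regions")
    z = np.empty((len(subjects), len(region_ids)))
    for si, ts in enumerate(subjects):
        seed_series = _mean_over(ts.data, np.asarray(seed_cluster_vertices))
        for ri, rid in enumerate(region_ids):
            reg_series = region_average(ts.data, atlas, rid)
            z[si, ri] = fisher_z(_corr(seed_series, reg_series, "time series"))
    t_stats = np.empty(len(region_ids))
    raw_p = np.empty(len(region_ids))
    for ri in range(len(region_ids)):
        t_stats[ri], raw_p[ri] = _one_sample_t_greater(z[:, ri])
    reject, adj = fdr_bh(raw_p, alpha=alpha)
    table = pd.DataFrame(
        {
            "region_id": region_ids,
            "region": [atlas.name(r) for r in region_ids],
            "statistic": t_stats,
            "raw_p": raw_p,
            "corrected_p": adj,
            "significant": reject,
        }
    )
    return SeedNetworkResult(table=table, mode="fmri", n=len(subjects), alpha=alpha)


def thickness_seed_network(
    stack,
    atlas: RegionAtlas,
    seed_cluster_vertices,
    z_threshold: float = 0.4,
) -> SeedNetworkResult:
    """Structural-covariance whole-brain connectivity of one seed sub-region.

    Group-level: the seed cluster's average thickness per subject is
    correlated across subjects with each region's average thickness;
    regions with Fisher z above ``z_threshold`` are significant. The
    reported one-sided p uses the null z ~ Normal(0, 1/sqrt(n - 3)).
    """
    from .connectivity import fisher_z

    if stack.n_subjects < 4:
        raise InputError("need at least 4 subjects")
    region_ids = atlas.region_ids
    if not region_ids:
        raise InputError("atlas names no regions")
    vert_by_subj = stack.data.T  # vertices x subjects
    seed_avg = _mean_over(vert_by_subj, np.asarray(seed_cluster_vertices))
    n = stack.n_subjects
    se = 1.0 / np.sqrt(n - 3)
    zs, raw_p = [], []
    for rid in region_ids:
        reg_avg = region_average(vert_by_subj, atlas, rid)
        zval = fisher_z(_corr(seed_avg, reg_avg, "thickness"))
        zs.append(zval)
        raw_p.append(float(stats.norm.sf(zval / se)))
    zs = np.array(zs)
    raw_p = np.array(raw_p)
    table = pd.DataFrame(
        {
            "region_id": region_ids,
            "region": [atlas.name(r) for r in region_ids],
            "statistic": zs,
            "raw_p": raw_p,
            "corrected_p": raw_p,
            "significant": zs > z_threshold,
        }
    )
    return SeedNetworkResult(
        table=table, mode="thickness", n=n, z_threshold=z_threshold
    )
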