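"""End-to-end orchestration: simulate -> ROI -> connectivity -> parcellate
-> select k -> compare -> seed network.

Every stage writes its artifact plus a JSON sidecar carrying the resolved
configuration hash and seed, so identical config + seed reproduce
bit-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .comparison import dice_overlap
from .connectivity import (
    group_sum,
    seed_correlation_fmri,
    seed_correlation_thickness,
    stability_map_fmri,
    stability_map_thickness,
)
from .exceptions import InputError
from .model_selection import select_k, silhouette_curve, split_half_vi
from .parcellation import (
    Parcellation,
    build_affinity,
    canonical_labels,
    spectral_parcellate,
    ward_parcellate,
)
from .roi import probabilistic_roi
from .seed_network import fmri_seed_network, thickness_seed_network
from .simulate import CohortConfig, generate_cohort

log = logging.getLogger("mfcparc")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run.

    Defaults are the analysis constants: ROI threshold 0.75, 5-fold
    stability resampling repeated 30 times, split-half VI repeated 100
    times over k = 2..10, FDR level 0.05, thickness z threshold 0.4.
    """

    out_dir: str = "mfcparc_run"
    cohort_dir: Optional[str] = None  # None -> simulate
    cohort: CohortConfig = field(default_factory=CohortConfig)
    algorithms: List[str] = field(default_factory=lambda: ["ward", "spectral"])
    k: int = 2
    k_values: List[int] = field(default_factory=lambda: list(range(2, 11)))
    n_repeats_vi: int = 100
    n_repeats_stability: int = 30
    n_folds: int = 5
    alpha: float = 0.05
    z_threshold: float = 0.4
    roi_threshold: float = 0.75
    rng_seed: int = 0
    run_stability: bool = True
    run_selection: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["fingerprint_matrix"] = self.cohort.fingerprint_matrix.tolist()
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**raw.pop("cohort", {}))
        try:
            return cls(cohort=cohort, **raw)
        except TypeError as exc:
            raise InputError(f"bad run configuration: {exc}") from exc


def _parcellate(matrix, algorithm: str, k: int, rng_seed: int) -> Parcellation:
    if algorithm == "ward":
        return ward_parcellate(matrix, k)
    if algorithm == "spectral":
        return spectral_parcellate(build_affinity(matrix), k, rng_seed=rng_seed)
    raise InputError(f"unknown algorithm {algorithm!r}")


def run_pipeline(config: RunConfig) -> Dict:
    """Execute the configured stages; returns a summary dict (also written
    as ``summary.json`` in the run directory)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash analysis parameters only; artifact locations do not change results
    hashed = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    chash = mio.config_hash(hashed)
    sidecar = {"config_hash": chash, "rng_seed": config.rng_seed}
    (out / "run_config.json").write_text(
        json.dumps({**config.to_dict(), "config_hash": chash}, indent=2, sort_keys=True)
    )
    summary: Dict = {"config_hash": chash}

    # --- cohort
    if config.cohort_dir is not None:
        cohort = mio.read_cohort(config.cohort_dir)
        log.info("stage=cohort source=%s", config.cohort_dir)
    else:
        cohort = generate_cohort(config.cohort)
        mio.write_cohort(cohort, out / "cohort")
        log.info("stage=simulate subjects=%d seed=%d",
                 cohort.config.n_subjects, cohort.config.rng_seed)

    # --- probabilistic ROI over seed vertices
    roi = probabilistic_roi(cohort.roi_masks, config.roi_threshold)
    seeds_used = cohort.seed_vertex_ids[roi.mask]
    if seeds_used.size < max(config.k, 2):
        raise InputError("ROI retains too few seed vertices to parcellate")
    mio._write_tsv(
        out / "roi.tsv",
        pd.DataFrame(
            {
                "vertex": cohort.seed_vertex_ids,
                "count": roi.counts,
                "in_mask": roi.mask.astype(int),
            }
        ),
    )
    summary["roi_n_vertices"] = int(seeds_used.size)
    log.info("stage=roi retained=%d/%d threshold=%g",
             seeds_used.size, roi.mask.size, config.roi_threshold)

    # --- connectivity
    targets = cohort.target_vertex_ids
    per_subject = [
        seed_correlation_fmri(ts, seeds_used, targets) for ts in cohort.timeseries
    ]
    group_fmri = group_sum(per_subject)
    group_thick = seed_correlation_thickness(cohort.thickness, seeds_used, targets)
    mio.write_matrix(group_fmri, out / "corr_fmri.tsv")
    mio.write_matrix(group_thick, out / "corr_thickness.tsv")
    log.info("stage=connect Ns=%d Nw=%d", group_fmri.n_seed, group_fmri.n_target)

    # --- stability
    if config.run_stability:
        stab_f = stability_map_fmri(
            per_subject,
            n_folds=config.n_folds,
            n_repeats=config.n_repeats_stability,
            rng_seed=config.rng_seed,
        )
        stab_t = stability_map_thickness(
            cohort.thickness,
            seeds_used,
            targets,
            n_folds=config.n_folds,
            n_repeats=config.n_repeats_stability,
            rng_seed=config.rng_seed,
        )
        summary["stability_fmri_mean"] = stab_f.mean
        summary["stability_thickness_mean"] = stab_t.mean
        log.info("stage=stability fmri=%.3f thickness=%.3f", stab_f.mean, stab_t.mean)

    # --- model selection (functional matrices, each configured algorithm)
    if config.run_selection:
        for algorithm in config.algorithms:
            vi = split_half_vi(
                per_subject,
                config.k_values,
                algorithm=algorithm,
                n_repeats=config.n_repeats_vi,
                rng_seed=config.rng_seed,
            )
            sil = silhouette_curve(
                per_subject, config.k_values, algorithm=algorithm,
                rng_seed=config.rng_seed,
            )
            sel = select_k(vi, sil, alpha=config.alpha)
            mio.write_vi_curve(vi, out / f"vi_{algorithm}.tsv")
            mio.write_silhouette_curve(sil, out / f"silhouette_{algorithm}.tsv")
            summary[f"selected_k_{algorithm}"] = sel.k
            summary[f"vi_plateau_k_{algorithm}"] = sel.vi_plateau_k
            log.info("stage=select-k algorithm=%s k=%d plateau=%s",
                     algorithm, sel.k, sel.vi_plateau_k)

    # --- parcellation, truth recovery and cross-modal agreement
    parcellations: Dict[str, Parcellation] = {}
    truth = Parcellation(
        labels=canonical_labels(cohort.truth_seed_labels[roi.mask]),
        k=cohort.config.n_clusters,
        algorithm="truth",
        seed_vertex_ids=seeds_used,
    )
    for algorithm in config.algorithms:
        for modality, matrix in (("fmri", group_fmri), ("thickness", group_thick)):
            p = _parcellate(matrix, algorithm, config.k, config.rng_seed)
            parcellations[f"{modality}_{algorithm}"] = p
            mio.write_parcellation(
                p, out / f"parcellation_{modality}_{algorithm}.tsv",
                rng_seed=config.rng_seed,
            )
            if p.k == truth.k:
                summary[f"dice_truth_{modality}_{algorithm}"] = dice_overlap(
                    p, truth
                ).mean_dice
        cross = dice_overlap(
            parcellations[f"fmri_{algorithm}"],
            parcellations[f"thickness_{algorithm}"],
        )
        summary[f"dice_cross_modal_{algorithm}"] = cross.mean_dice
        log.info("stage=compare algorithm=%s cross_modal_dice=%.3f",
                 algorithm, cross.mean_dice)

    # --- whole-brain seed network per sub-region (reference: fMRI + first algorithm)
    ref = parcellations[f"fmri_{config.algorithms[0]}"]
    for label in range(1, ref.k + 1):
        cluster_vertices = ref.cluster_vertices(label)
        res_f = fmri_seed_network(
            cohort.timeseries, cohort.atlas, cluster_vertices, alpha=config.alpha
        )
        res_t = thickness_seed_network(
            cohort.thickness, cohort.atlas, cluster_vertices,
            z_threshold=config.z_threshold,
        )
        mio.write_seed_network(res_f, out / f"seed_network_fmri_cluster{label}.tsv")
        mio.write_seed_network(res_t, out / f"seed_network_thickness_cluster{label}.tsv")
        summary[f"n_significant_fmri_cluster{label}"] = int(
            res_f.table["significant"].sum()
        )
        summary[f"n_significant_thickness_cluster{label}"] = int(
            res_t.table["significant"].sum()
        )
        log.info(
            "stage=seed-network cluster=%d fmri_sig=%d thickness_sig=%d",
            label,
            summary[f"n_significant_fmri_cluster{label}"],
            summary[f"n_significant_thickness_cluster{label}"],
        )

    (out / "summary.json").write_text(
        json.dumps({**summary, **sidecar}, indent=2, sort_keys=True, default=mio._jsonable)
    )
    return summary
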