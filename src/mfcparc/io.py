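"""Headered-TSV and JSON interchange, plus optional imaging-format readers.

Native formats are diffable text: per-subject time-series TSV (vertices x
timepoints), thickness TSV (subjects x vertices), mask TSV, correlation
matrices as TSV with a JSON sidecar carrying modality and aggregation
metadata. Vertex indices are 0-based in files; cluster labels are 1-based.
Floats are written with 17 significant digits so files round-trip
bit-identically.

Read-only helpers accept GIFTI per-vertex data and NIfTI volumes and
convert them to the internal vertex-table representation; writers never
emit imaging formats.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import List

import numpy as np
import pandas as pd

from .connectivity import SeedCorrelationMatrix, SubjectTimeSeries, ThicknessStack
from .exceptions import InputError
from .model_selection import SilhouetteCurve, VICurve
from .parcellation import Parcellation
from .seed_network import RegionAtlas, SeedNetworkResult
from .simulate import CohortConfig, SyntheticCohort

FLOAT_FMT = "%.17g"


def _write_tsv(path: Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def config_hash(obj) -> str:
    """Stable hash of a JSON-serialisable configuration."""
    blob = json.dumps(obj, sort_keys=True, default=_jsonable).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON-serialisable: {type(x)}")


# ---------------------------------------------------------------- cohorts

def write_cohort(cohort: SyntheticCohort, path) -> Path:
    """Write a cohort directory: manifest + TSV tables."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    c = cohort.config
    manifest = {
        "n_subjects": c.n_subjects,
        "n_seed_vertices": c.n_seed_vertices,
        "n_target_vertices": c.n_target_vertices,
        "n_timepoints": c.n_timepoints,
        "n_clusters": c.n_clusters,
        "n_target_modules": c.n_target_modules,
        "fingerprint_matrix": c.fingerprint_matrix.tolist(),
        "noise_sd_fmri": c.noise_sd_fmri,
        "noise_sd_thickness": c.noise_sd_thickness,
        "factor_loading": c.factor_loading,
        "roi_flip_prob": c.roi_flip_prob,
        "rng_seed": c.rng_seed,
        "subject_ids": [ts.subject_id for ts in cohort.timeseries],
        "vertex_indexing": "0-based; seeds first, then targets",
        "region_names": {str(k): v for k, v in cohort.atlas.region_names.items()},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    for ts in cohort.timeseries:
        frame = pd.DataFrame(
            ts.data, columns=[f"t{j}" for j in range(ts.n_timepoints)]
        )
        frame.insert(0, "vertex", np.arange(ts.n_vertices))
        _write_tsv(path / f"timeseries_{ts.subject_id}.tsv", frame)
    th = pd.DataFrame(
        cohort.thickness.data,
        columns=[f"v{j}" for j in range(cohort.thickness.n_vertices)],
    )
    th.insert(0, "subject", list(cohort.thickness.subject_ids))
    _write_tsv(path / "thickness.tsv", th)
    masks = pd.DataFrame(
        cohort.roi_masks.astype(int),
        columns=[f"v{j}" for j in range(cohort.roi_masks.shape[1])],
    )
    masks.insert(0, "subject", list(cohort.thickness.subject_ids))
    _write_tsv(path / "roi_masks.tsv", masks)
    truth = pd.DataFrame(
        {
            "vertex": np.concatenate(
                [cohort.seed_vertex_ids, cohort.target_vertex_ids]
            ),
            "kind": ["seed"] * len(cohort.seed_vertex_ids)
            + ["target"] * len(cohort.target_vertex_ids),
            "label": np.concatenate(
                [cohort.truth_seed_labels, cohort.truth_target_modules]
            ),
        }
    )
    _write_tsv(path / "truth_labels.tsv", truth)
    return path


def read_cohort(path) -> SyntheticCohort:
    """Read a cohort directory written by :func:`write_cohort`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    config = CohortConfig(
        n_subjects=manifest["n_subjects"],
        n_seed_vertices=manifest["n_seed_vertices"],
        n_target_vertices=manifest["n_target_vertices"],
        n_timepoints=manifest["n_timepoints"],
        n_clusters=manifest["n_clusters"],
        n_target_modules=manifest["n_target_modules"],
        fingerprint_matrix=np.array(manifest["fingerprint_matrix"]),
        noise_sd_fmri=manifest["noise_sd_fmri"],
        noise_sd_thickness=manifest["noise_sd_thickness"],
        factor_loading=manifest["factor_loading"],
        roi_flip_prob=manifest["roi_flip_prob"],
        rng_seed=manifest["rng_seed"],
    )
    timeseries: List[SubjectTimeSeries] = []
    for sid in manifest["subject_ids"]:
        frame = pd.read_csv(path / f"timeseries_{sid}.tsv", sep="\t", float_precision="round_trip")
        timeseries.append(
            SubjectTimeSeries(
                data=frame.drop(columns="vertex").to_numpy(), subject_id=sid
            )
        )
    th = pd.read_csv(path / "thickness.tsv", sep="\t", float_precision="round_trip")
    thickness = ThicknessStack(
        data=th.drop(columns="subject").to_numpy(),
        subject_ids=th["subject"].tolist(),
    )
    masks = pd.read_csv(path / "roi_masks.tsv", sep="\t", float_precision="round_trip")
    roi_masks = masks.drop(columns="subject").to_numpy().astype(bool)
    truth = pd.read_csv(path / "truth_labels.tsv", sep="\t", float_precision="round_trip")
    seed_labels = truth.loc[truth["kind"] == "seed", "label"].to_numpy()
    target_modules = truth.loc[truth["kind"] == "target", "label"].to_numpy()
    ns = config.n_seed_vertices
    region_of = np.zeros(ns + config.n_target_vertices, dtype=int)
    region_of[ns:] = target_modules
    atlas = RegionAtlas(
        region_of=region_of,
        region_names={int(k): v for k, v in manifest["region_names"].items()},
    )
    return SyntheticCohort(
        config=config,
        timeseries=timeseries,
        thickness=thickness,
        roi_masks=roi_masks,
        truth_seed_labels=seed_labels,
        truth_target_modules=target_modules,
        atlas=atlas,
    )


# ---------------------------------------------------------------- matrices

def write_matrix(m: SeedCorrelationMatrix, path) -> Path:
    """Matrix as TSV (rows = seed vertices) with a JSON metadata sidecar."""
    path = Path(path)
    frame = pd.DataFrame(m.z, columns=[f"v{int(t)}" for t in m.target_vertex_ids])
    frame.insert(0, "seed_vertex", m.seed_vertex_ids)
    _write_tsv(path, frame)
    sidecar = {
        "modality": m.modality,
        "n_aggregated": int(m.n_aggregated),
        "n_seed": int(m.n_seed),
        "n_target": int(m.n_target),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_matrix(path) -> SeedCorrelationMatrix:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    target_ids = np.array([int(c[1:]) for c in frame.columns if c != "seed_vertex"])
    return SeedCorrelationMatrix(
        z=frame.drop(columns="seed_vertex").to_numpy(),
        seed_vertex_ids=frame["seed_vertex"].to_numpy(),
        target_vertex_ids=target_ids,
        modality=sidecar["modality"],
        n_aggregated=sidecar["n_aggregated"],
    )


# ------------------------------------------------------------ parcellations

def write_parcellation(p: Parcellation, path, rng_seed=None) -> Path:
    path = Path(path)
    _write_tsv(
        path,
        pd.DataFrame({"vertex_id": p.seed_vertex_ids, "label": p.labels}),
    )
    sidecar = {"k": int(p.k), "algorithm": p.algorithm}
    if rng_seed is not None:
        sidecar["rng_seed"] = int(rng_seed)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


def read_parcellation(path) -> Parcellation:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return Parcellation(
        labels=frame["label"].to_numpy(),
        k=sidecar["k"],
        algorithm=sidecar["algorithm"],
        seed_vertex_ids=frame["vertex_id"].to_numpy(),
    )


# ----------------------------------------------------------------- curves

def write_vi_curve(curve: VICurve, path) -> Path:
    path = Path(path)
    rows = []
    for k, samples in zip(curve.k_values, curve.vi_samples):
        rows.append(
            {"k": k, "mean_vi": samples.mean(),
             "samples": ",".join(FLOAT_FMT % s for s in samples)}
        )
    _write_tsv(path, pd.DataFrame(rows))
    return path


def write_silhouette_curve(curve: SilhouetteCurve, path) -> Path:
    path = Path(path)
    rows = []
    for k, samples in zip(curve.k_values, curve.per_subject_values):
        rows.append(
            {"k": k, "mean_silhouette": samples.mean(),
             "samples": ",".join(FLOAT_FMT % s for s in samples)}
        )
    _write_tsv(path, pd.DataFrame(rows))
    return path


def write_seed_network(result: SeedNetworkResult, path) -> Path:
    path = Path(path)
    _write_tsv(path, result.table)
    sidecar = {
        "mode": result.mode,
        "n": int(result.n),
        "alpha": result.alpha,
        "z_threshold": result.z_threshold,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return path


# --------------------------------------------- optional imaging-format input

def read_gifti_vertex_data(path) -> np.ndarray:
    """Per-vertex data arrays from a GIFTI file, stacked vertices x arrays."""
    import nibabel as nib

    img = nib.load(str(path))
    arrays = [np.asarray(d.data, dtype=float) for d in img.darrays]
    if not arrays:
        raise InputError(f"no data arrays in GIFTI file {path}")
    return np.column_stack(arrays)


def read_nifti_mask(path, threshold: float = 0.5) -> np.ndarray:
    """Flattened boolean mask from a NIfTI volume (voxels as 'vertices')."""
    import nibabel as nib

    img = nib.load(str(path))
    return (np.asarray(img.dataobj, dtype=float).ravel() > threshold)
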