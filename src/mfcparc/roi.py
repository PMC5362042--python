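"""Probabilistic seed ROI from per-subject binary masks.

Individual delineations of the same cortical region disagree at the edges;
summing the binary masks and thresholding the per-vertex subject count
yields a probabilistic group ROI. A vertex is retained when at least a
fraction ``threshold_fraction`` of subjects include it (inclusive cut, so
9 of 12 passes a 75% threshold).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InputError

__all__ = ["ProbabilisticROI", "probabilistic_roi"]


@dataclass
class ProbabilisticROI:
    counts: np.ndarray  # per-vertex number of subjects containing the vertex
    n_subjects: int
    threshold_fraction: float
    mask: np.ndarray  # per-vertex boolean

    @property
    def vertex_ids(self) -> np.ndarray:
        """Indices of retained vertices."""
        return np.flatnonzero(self.mask)


def probabilistic_roi(
    masks: Sequence[np.ndarray], threshold_fraction: float = 0.75
) -> ProbabilisticROI:
    """Sum binary masks and keep vertices present in >= threshold of subjects.

    Parameters
    ----------
    masks
        Per-subject boolean vertex masks, all the same length. A 2-D
        subjects x vertices boolean array is also accepted.
    threshold_fraction
        Retention cut in (0, 1]; the comparison is inclusive.
    """
    try:
        arr = np.asarray(masks)
    except ValueError as exc:
        raise InputError(f"masks must all have the same length: {exc}") from exc
    if arr.size == 0:
        raise InputError("need at least one mask")
    if arr.ndim != 2:
        raise InputError("masks must all have the same length")
    if not (0 < threshold_fraction <= 1):
        raise InputError("threshold_fraction must lie in (0, 1]")
    arr = arr.astype(bool)
    n = arr.shape[0]
    counts = arr.sum(axis=0)
    mask = counts / n >= threshold_fraction
    if not mask.any():
        warnings.warn(
            "probabilistic ROI is empty at threshold "
            f"{threshold_fraction:g} over {n} subjects",
            stacklevel=2,
        )
    return ProbabilisticROI(
        counts=counts.astype(int),
        n_subjects=n,
        threshold_fraction=float(threshold_fraction),
        mask=mask,
    )
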