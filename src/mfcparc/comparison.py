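"""Agreement between parcellations, and overlap with an external atlas.

Cluster ids carry no meaning across runs, so two parcellations are first
matched by a bijection maximising total vertex overlap (Hungarian
assignment on the contingency table); the dice coefficient
``2|A ∩ B| / (|A| + |B|)`` is then computed per matched pair of
sub-regions and averaged without weighting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment

from .exceptions import InputError
from .parcellation import Parcellation

__all__ = ["LabelMatching", "DiceReport", "match_labels", "dice_overlap", "atlas_overlap"]


@dataclass
class LabelMatching:
    mapping: Dict[int, int]  # cluster id in p -> matched cluster id in q
    overlap_table: np.ndarray  # k x k contingency counts


@dataclass
class DiceReport:
    per_cluster_dice: Dict[Tuple[int, int], float]  # (p label, q label) -> dice
    mean_dice: float


def _contingency(p: Parcellation, q: Parcellation) -> np.ndarray:
    cont = np.zeros((p.k, q.k), dtype=int)
    np.add.at(cont, (p.labels - 1, q.labels - 1), 1)
    return cont


def match_labels(p: Parcellation, q: Parcellation) -> LabelMatching:
    """Optimal bijection between cluster ids of two same-k parcellations.

    Maximises total vertex overlap (Hungarian assignment on the negated
    contingency table). Ties in total overlap are broken towards the
    assignment with the larger summed per-pair dice — a transpose-symmetric
    criterion, so the induced dice report does not depend on argument order.
    """
    if not np.array_equal(p.seed_vertex_ids, q.seed_vertex_ids):
        raise InputError("parcellations cover different seed vertex sets")
    if p.k != q.k:
        raise InputError(f"cannot match parcellations with k={p.k} and k={q.k}")
    cont = _contingency(p, q)
    sizes_p = cont.sum(axis=1, keepdims=True)
    sizes_q = cont.sum(axis=0, keepdims=True)
    dice = 2.0 * cont / (sizes_p + sizes_q)
    # overlaps are integers >= 1 apart; dice sum < k, so the perturbation
    # can only separate assignments whose total overlap ties
    rows, cols = linear_sum_assignment(-(cont + dice / (4.0 * p.k)))
    mapping = {int(r) + 1: int(c) + 1 for r, c in zip(rows, cols)}
    return LabelMatching(mapping=mapping, overlap_table=cont)


def dice_overlap(p: Parcellation, q: Parcellation) -> DiceReport:
    """Per-matched-cluster and mean dice coefficients between parcellations."""
    matching = match_labels(p, q)
    per: Dict[Tuple[int, int], float] = {}
    for pl, ql in matching.mapping.items():
        inter = matching.overlap_table[pl - 1, ql - 1]
        size_p = matching.overlap_table[pl - 1].sum()
        size_q = matching.overlap_table[:, ql - 1].sum()
        per[(pl, ql)] = 2.0 * inter / (size_p + size_q)
    return DiceReport(
        per_cluster_dice=per, mean_dice=float(np.mean(list(per.values())))
    )


def atlas_overlap(p: Parcellation, region_mask: np.ndarray) -> Dict[int, float]:
    """Fraction of each cluster lying inside an external region mask.

    ``region_mask`` is a boolean array over the same seed vertices
    (positionally aligned with ``p.seed_vertex_ids``).
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.shape != p.labels.shape:
        raise InputError("region mask length does not match the seed vertex set")
    return {
        int(lab): float(region_mask[p.labels == lab].mean())
        for lab in range(1, p.k + 1)
    }
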