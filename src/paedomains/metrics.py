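"""Intersection-over-Union scoring of a segmentation against a reference.

Predicted and reference domains are matched one-to-one by optimal
assignment (maximizing summed IoU); the mean IoU divides the matched sum by
max(n_pred, n_ref), so surplus domains on either side count as zero. This
penalizes over- and under-segmentation symmetrically. Unassigned residues
belong to no domain and so contribute to no intersection or union.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .pae_io import ResidueTable
from .segmentation import Domain, Segmentation


@dataclass(frozen=True)
class IouReport:
    """Matched (predicted, reference) domain pairs and the overall mean IoU."""

    per_pair: tuple[tuple[int, int, float], ...]
    mean_iou: float
    n_pred: int
    n_ref: int


def domain_iou(a: Domain, b: Domain, table: ResidueTable | None = None) -> float:
    """|residues(a) & residues(b)| / |residues(a) | residues(b)|."""
    ra, rb = a.residues(table), b.residues(table)
    union = ra | rb
    if not union:
        return 0.0
    return len(ra & rb) / len(union)


def match_and_score(pred: Segmentation, ref: Segmentation,
                    table: ResidueTable | None = None) -> IouReport:
    """Optimal one-to-one matching of predicted to reference domains.

    Returns the matched pairs (with their IoU) and
    mean_iou = (sum of matched IoUs) / max(n_pred, n_ref).
    """
    n_pred, n_ref = len(pred.domains), len(ref.domains)
    if n_pred == 0 or n_ref == 0:
        mean = 1.0 if n_pred == n_ref else 0.0
        return IouReport((), mean, n_pred, n_ref)
    iou = np.zeros((n_pred, n_ref))
    for i, dp in enumerate(pred.domains):
        for j, dr in enumerate(ref.domains):
            iou[i, j] = domain_iou(dp, dr, table)
    rows, cols = linear_sum_assignment(iou, maximize=True)
    pairs = tuple((int(i), int(j), float(iou[i, j])) for i, j in zip(rows, cols))
    mean = float(iou[rows, cols].sum() / max(n_pred, n_ref))
    return IouReport(pairs, mean, n_pred, n_ref)
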