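"""Logistic contrast transform: PAE matrix -> weighted residue network.

Each residue is a node; every pair (i, j) gets an edge of weight

    w_ij = 1 / (1 + exp(PAE_ij - T))

where T is the "contrast" threshold, a soft cut-off in Angstroms: pairs with
PAE below T map to weights above 0.5 (confident, likely intra-domain), pairs
above T map below 0.5. Raw PAE is asymmetric, so the matrix is symmetrized
by the arithmetic mean before the transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .errors import DegenerateInputError
from .pae_io import PaeMatrix

#: Recommended soft cut-off (A); useful exploration range is roughly 0-4.
DEFAULT_THRESHOLD = 2.0

# expit underflows to exactly 0 for arguments below ~-745; clamp to the
# smallest normal float so weights stay strictly positive and the network
# stays fully connected.
_WEIGHT_FLOOR = np.finfo(float).tiny

ContrastThreshold = float


@dataclass(frozen=True)
class ResidueGraph:
    """Fully connected weighted undirected graph over residues.

    ``weights`` is symmetric with zero diagonal and off-diagonal entries
    strictly in (0, 1).
    """

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError(f"weight matrix must be square, got {w.shape}")
        if not np.array_equal(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero (no self-loops)")
        off = w[~np.eye(w.shape[0], dtype=bool)]
        if np.any(off <= 0) or np.any(off >= 1):
            raise ValueError("off-diagonal weights must lie strictly in (0, 1)")
        object.__setattr__(self, "weights", w)

    @property
    def n(self) -> int:
        return self.weights.shape[0]


def symmetrize(pae: PaeMatrix) -> PaeMatrix:
    """Average PAE_ij with PAE_ji so each residue pair has a single value."""
    sym = (pae.values + pae.values.T) / 2.0
    return PaeMatrix(sym, dialect=pae.dialect, max_pae=pae.max_pae)


def logistic_weight(pae_value, T: float = DEFAULT_THRESHOLD):
    """Edge weight 1/(1+exp(pae - T)), overflow-safe, clamped into (0, 1).

    Accepts scalars or arrays. Strictly decreasing in pae_value; equals 0.5
    exactly at pae_value == T.
    """
    w = expit(np.asarray(T, dtype=float) - np.asarray(pae_value, dtype=float))
    return np.clip(w, _WEIGHT_FLOOR, 1.0 - np.finfo(float).epsneg)


def build_graph(pae: PaeMatrix, T: float = DEFAULT_THRESHOLD,
                prune_below: float = 0.0) -> ResidueGraph:
    """Build the fully connected residue network from a PAE matrix.

    Parameters
    ----------
    pae : raw (possibly asymmetric) PAE matrix.
    T : contrast threshold in Angstroms.
    prune_below : efficiency knob; weights below this are floored to the
        minimum positive weight rather than removed, keeping the graph
        connected. Default 0 (off).
    """
    if pae.n < 2:
        raise DegenerateInputError("need at least 2 residues to build a network")
    sym = symmetrize(pae)
    weights = np.asarray(logistic_weight(sym.values, T), dtype=float)
    if prune_below > 0:
        weights[weights < prune_below] = _WEIGHT_FLOOR
    np.fill_diagonal(weights, 0.0)
    # enforce exact symmetry despite floating arithmetic
    weights = np.minimum(weights, weights.T)
    return ResidueGraph(weights)


def unassignable_residues(graph: ResidueGraph) -> frozenset[int]:
    """Residues with no confident partner: every edge weight below 0.5.

    A weight of 0.5 is the logistic midpoint, i.e. symmetrized PAE equal to
    the contrast threshold T. A residue whose PAE to *every* other residue
    exceeds T (a disordered high-PAE band) carries no positive evidence for
    membership in any domain and is reported as unassigned rather than
    attached to whichever cluster the optimizer drifts it into.
    """
    w = graph.weights.copy()
    np.fill_diagonal(w, -np.inf)
    return frozenset(int(i) for i in np.flatnonzero(w.max(axis=1) < 0.5))
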