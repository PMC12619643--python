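"""The end-to-end segmentation pipeline.

Wires the stages together with the recommended defaults (contrast
threshold 2 Å, resolution 0.7): PAE matrix -> logistic-weighted residue
network -> Leiden partition -> minimum-size filtering and interval mapping.
Residues with no confident partner (every symmetrized PAE above T) are
reported as unassigned rather than clustered; see
:func:`paedomains.network.unassignable_residues`.
"""

from __future__ import annotations

from dataclasses import dataclass

from .clustering import ClusterAssignment, ClusterParams, leiden_cluster
from .network import DEFAULT_THRESHOLD, ResidueGraph, build_graph, unassignable_residues
from .pae_io import PaeMatrix, ResidueTable
from .segmentation import DEFAULT_MIN_SIZE, Segmentation, clusters_to_segmentation


@dataclass(frozen=True)
class SegmentationResult:
    """Everything one run produces: the graph, the raw partition, the domains."""

    graph: ResidueGraph
    assignment: ClusterAssignment
    segmentation: Segmentation


def segment_pae(pae: PaeMatrix,
                threshold: float = DEFAULT_THRESHOLD,
                params: ClusterParams | None = None,
                min_size: int = DEFAULT_MIN_SIZE,
                residues: ResidueTable | None = None,
                filter_unassignable: bool = True) -> SegmentationResult:
    """Segment one protein from its PAE matrix.

    Parameters
    ----------
    pae : parsed PAE matrix (any dialect).
    threshold : contrast threshold T in Angstroms (soft cut-off).
    params : Leiden parameters; defaults to resolution 0.7, modularity,
        seed 0.
    min_size : smallest cluster reported as a domain.
    residues : optional residue table for author numbering / chain IDs.
    filter_unassignable : send residues without any confident partner to
        unassigned instead of clustering them.
    """
    if params is None:
        params = ClusterParams()
    graph = build_graph(pae, threshold)
    assignment = leiden_cluster(graph, params)
    exclude = unassignable_residues(graph) if filter_unassignable else frozenset()
    seg = clusters_to_segmentation(assignment, residues, min_size, exclude=exclude)
    seg = Segmentation(seg.domains, seg.unassigned, params_used={
        "threshold": threshold,
        "resolution": params.resolution,
        "objective": params.objective,
        "min_size": min_size,
        "seed": params.seed,
        "quality": assignment.quality,
    })
    return SegmentationResult(graph, assignment, seg)
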