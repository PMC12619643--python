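"""Shared fixtures: synthetic structure files and hand-built graphs.

All structure fixtures are generated programmatically (synthetic poly-ALA
models), never read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from paedomains import ResidueGraph


def make_pdb(chains: dict[str, list[tuple[int, str, float]]]) -> str:
    """Synthetic poly-ALA PDB text.

    ``chains`` maps chain id -> list of (author residue number, insertion
    code, B-factor). Three atoms per residue; coordinates are arbitrary.
    """
    lines = []
    serial = 1
    for cid, residues in chains.items():
        for num, icode, b in residues:
            for name in ("N", "CA", "C"):
                x, y, z = serial * 1.1, serial * 0.3, 0.0
                lines.append(
                    f"ATOM  {serial:5d}  {name:<3s} ALA {cid:1s}{num:4d}"
                    f"{icode or ' ':1s}   {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{b:6.2f}          {name[0]:>2s}"
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    return "\n".join(lines) + "\n"


def make_mmcif(chains: dict[str, list[tuple[int, str, float]]]) -> str:
    """Same synthetic model as :func:`make_pdb`, as mmCIF text."""
    import gemmi

    st = gemmi.read_pdb_string(make_pdb(chains))
    st.setup_entities()
    return st.make_mmcif_document().as_string()


@pytest.fixture
def three_residue_pdb() -> str:
    return make_pdb({"A": [(1, "", 90.1), (2, "", 55.2), (3, "", 30.3)]})


@pytest.fixture
def two_chain_mmcif() -> str:
    return make_mmcif({
        "A": [(i, "", 80.0) for i in range(1, 6)],
        "B": [(i, "", 70.0) for i in range(1, 5)],
    })


def two_clique_graph(strong: float = 0.88, weak: float = 1e-9) -> ResidueGraph:
    """Two 5-cliques joined by near-zero edges; planted optimum is obvious."""
    w = np.full((10, 10), weak)
    w[:5, :5] = strong
    w[5:, 5:] = strong
    np.fill_diagonal(w, 0.0)
    return ResidueGraph(w)


def single_clique_graph(n: int = 4, weight: float = 1.0 - 1e-12) -> ResidueGraph:
    w = np.full((n, n), weight)
    np.fill_diagonal(w, 0.0)
    return ResidueGraph(w)
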