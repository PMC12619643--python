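"""Reading PAE matrices and residue metadata.

Three JSON dialects of the PAE matrix circulate:

* ``afdb`` — AlphaFold DB: ``{"predicted_aligned_error": [[...]],
  "max_predicted_aligned_error": 31.75}``, usually wrapped in a one-element
  top-level list.
* ``colabfold`` — ColabFold: ``{"pae": [[...]]}``.
* ``pairlist`` — legacy AlphaFold2 outputs: parallel arrays ``residue1``,
  ``residue2``, ``distance`` listing (i, j, PAE_ij) with 1-based indices.

Residue metadata (chain, author numbering, pLDDT from the B-factor column)
is read from PDB/mmCIF files with gemmi.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

import gemmi
import numpy as np

from .errors import (
    DialectError,
    EmptyStructureError,
    PaeDomainError,
    PaeParseError,
    PaeShapeError,
    ReconciliationError,
    StructureFormatError,
)

Source = Union[str, Path, bytes, io.IOBase]

AFDB_MAX_PAE = 31.75


@dataclass(frozen=True)
class PaeMatrix:
    """An n-by-n predicted-aligned-error matrix in Angstroms.

    The diagonal holds whatever the file declared (typically 0 but never
    forced); the matrix may be asymmetric, as raw PAE is.
    """

    values: np.ndarray
    dialect: str = "afdb"
    max_pae: float | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise PaeShapeError(f"PAE matrix must be square, got shape {values.shape}")
        if values.shape[0] < 2:
            raise PaeShapeError(f"PAE matrix needs at least 2 residues, got {values.shape[0]}")
        if np.any(values < 0):
            raise PaeDomainError("PAE matrix contains negative entries")
        if self.max_pae is not None and np.any(values > self.max_pae):
            raise PaeDomainError(
                f"PAE entries exceed declared max_pae={self.max_pae}"
            )
        object.__setattr__(self, "values", values)

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ResidueEntry:
    chain_id: str
    author_seq_id: int
    insertion_code: str = ""
    plddt: float = 0.0


@dataclass(frozen=True)
class ResidueTable:
    """Per-residue metadata in file order; aligns PAE indices to a structure."""

    entries: tuple[ResidueEntry, ...]

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        keys = [(e.chain_id, e.author_seq_id, e.insertion_code) for e in entries]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (chain, author number, insertion code) triples")
        object.__setattr__(self, "entries", entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, i):
        return self.entries[i]

    @property
    def chain_ids(self) -> set[str]:
        return {e.chain_id for e in self.entries}

    @property
    def plddt(self) -> np.ndarray:
        return np.array([e.plddt for e in self.entries])


def _read_bytes(source: Source) -> bytes:
    if isinstance(source, bytes):
        return source
    if isinstance(source, (str, Path)):
        return Path(source).read_bytes()
    data = source.read()
    return data if isinstance(data, bytes) else data.encode()


def _densify_pairlist(res1: list, res2: list, dist: list, max_pae: float | None) -> np.ndarray:
    """Place sparse (i, j, PAE) triples into a dense 1-based-indexed matrix.

    Missing pairs are imputed conservatively: the declared max_pae if present,
    else the largest observed distance (treat unknown as unconfident).
    """
    if not (len(res1) == len(res2) == len(dist)):
        raise PaeShapeError("residue1/residue2/distance arrays differ in length")
    if len(res1) == 0:
        raise PaeShapeError("empty pair list")
    n = int(max(max(res1), max(res2)))
    fill = float(max_pae) if max_pae is not None else float(max(dist))
    values = np.full((n, n), fill, dtype=float)
    for i, j, d in zip(res1, res2, dist):
        values[int(i) - 1, int(j) - 1] = float(d)
    return values


def parse_pae_json(source: Source) -> PaeMatrix:
    """Parse a PAE matrix from any of the supported JSON dialects.

    Dialect is auto-detected by key inspection; a top-level one-element list
    (the AlphaFold DB convention) is unwrapped first.
    """
    raw = _read_bytes(source)
    try:
        doc = json.loads(raw.decode("utf-8"))
    except json.JSONDecodeError as exc:
        raise PaeParseError(f"malformed JSON at byte offset {exc.pos}: {exc.msg}") from exc
    if isinstance(doc, list):
        if len(doc) != 1:
            raise DialectError(f"top-level list has {len(doc)} elements, expected 1")
        doc = doc[0]
    if not isinstance(doc, dict):
        raise DialectError(f"expected JSON object, got {type(doc).__name__}")

    max_pae = doc.get("max_predicted_aligned_error")
    if "predicted_aligned_error" in doc:
        values, dialect = doc["predicted_aligned_error"], "afdb"
    elif "pae" in doc:
        values, dialect = doc["pae"], "colabfold"
    elif "residue1" in doc:
        try:
            values = _densify_pairlist(
                doc["residue1"], doc["residue2"], doc["distance"], max_pae
            )
        except KeyError as exc:
            raise DialectError(f"pairlist dialect missing key {exc}") from exc
        dialect = "pairlist"
    else:
        raise DialectError(
            "unrecognized PAE JSON dialect; keys found: " + ", ".join(sorted(doc))
        )

    arr = np.asarray(values, dtype=object)
    if arr.ndim != 2:
        raise PaeShapeError("PAE matrix is ragged or not two-dimensional")
    return PaeMatrix(arr.astype(float), dialect=dialect,
                     max_pae=None if max_pae is None else float(max_pae))


def write_pae_json(pae: PaeMatrix) -> bytes:
    """Serialize to normalized afdb-dialect JSON (one-element top-level list)."""
    doc = {"predicted_aligned_error": pae.values.tolist()}
    if pae.max_pae is not None:
        doc["max_predicted_aligned_error"] = pae.max_pae
    return json.dumps([doc]).encode()


def _load_structure(raw: bytes, format: str) -> gemmi.Structure:
    text = raw.decode("utf-8", errors="replace")
    if format == "auto":
        stripped = text.lstrip()
        format = "mmcif" if stripped.startswith("data_") or stripped.startswith("#") else "pdb"
    try:
        if format == "pdb":
            st = gemmi.read_pdb_string(text)
        elif format == "mmcif":
            block = gemmi.cif.read_string(text).sole_block()
            st = gemmi.make_structure_from_block(block)
        else:
            raise StructureFormatError(f"unknown structure format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"could not read structure as {format}: {exc}") from exc
    st.setup_entities()
    return st


def _polymer_residues(st: gemmi.Structure) -> Iterable[tuple[str, gemmi.Residue]]:
    """Yield (chain_id, residue) for polymer residues in file order.

    Waters, ligands and other hetero records are skipped: the network nodes
    are residues of the polymer chains only.
    """
    if len(st) == 0:
        return
    model = st[0]
    for chain in model:
        polymer = chain.get_polymer()
        polymer_names = {(r.seqid.num, r.seqid.icode, r.name) for r in polymer}
        for res in chain:
            if (res.seqid.num, res.seqid.icode, res.name) in polymer_names:
                yield chain.name, res


def parse_structure(source: Source, format: str = "auto") -> ResidueTable:
    """Read per-residue chain, author numbering and pLDDT from PDB/mmCIF.

    AlphaFold models store pLDDT in the B-factor column; the first atom of
    each residue is taken as the residue value. Multi-chain structures are
    concatenated in file order, matching the joint PAE matrix that
    AlphaFold-Multimer emits.
    """
    raw = _read_bytes(source)
    st = _load_structure(raw, format)
    entries = []
    for chain_id, res in _polymer_residues(st):
        icode = res.seqid.icode.strip()
        plddt = res[0].b_iso if len(res) else 0.0
        entries.append(ResidueEntry(chain_id, res.seqid.num, icode, float(plddt)))
    if not entries:
        raise EmptyStructureError("structure contains no polymer residues")
    return ResidueTable(tuple(entries))


def reconcile(pae: PaeMatrix, residues: ResidueTable) -> ResidueTable:
    """Check that the matrix and residue table describe the same protein."""
    if pae.n != len(residues):
        raise ReconciliationError(
            f"PAE matrix has {pae.n} residues but structure has {len(residues)}"
        )
    return residues


def default_residue_table(n: int) -> ResidueTable:
    """Residue table for matrix-only input: single unnamed chain, numbers 1..n."""
    return ResidueTable(tuple(ResidueEntry("", i + 1) for i in range(n)))
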