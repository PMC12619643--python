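"""Mapping cluster labels to residue intervals and domain choppings.

A *domain* is a set of residue intervals (a discontinuous domain has more
than one segment); a *chopping string* is the CATH-style text encoding:
segments are "start-end" ranges, "_" joins segments of one domain, ","
separates domains, and a "C:" chain prefix appears for multi-chain inputs,
e.g. ``"1-3_6-7,4-5"``. Clusters smaller than ``min_size`` are not reported
as domains; their residues become *unassigned*.
"""

from __future__ import annotations

import csv
import io
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi

from .clustering import ClusterAssignment
from .errors import ChoppingParseError, ReconciliationError
from .pae_io import (
    ResidueEntry,
    ResidueTable,
    Source,
    _load_structure,
    _polymer_residues,
    _read_bytes,
    default_residue_table,
)

#: Default minimum cluster size (residues) reported as a domain.
DEFAULT_MIN_SIZE = 10

ResidueKey = tuple[str, int, str]  # (chain_id, author_seq_id, insertion_code)


@dataclass(frozen=True)
class Segment:
    """One contiguous run of residues, 1-based author numbering, inclusive."""

    chain_id: str
    start: int
    end: int
    start_icode: str = ""
    end_icode: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")


@dataclass(frozen=True)
class Domain:
    """A domain: one or more (possibly discontinuous) segments."""

    segments: tuple[Segment, ...]
    residue_count: int

    def residues(self, table: ResidueTable | None = None) -> frozenset[ResidueKey]:
        """The residue-key set covered by this domain.

        With a residue table, ranges are resolved by file order (so
        insertion codes are handled); without one, arithmetically.
        """
        if table is None:
            keys = set()
            for seg in self.segments:
                keys.update((seg.chain_id, num, "") for num in range(seg.start, seg.end + 1))
            return frozenset(keys)
        order = [(e.chain_id, e.author_seq_id, e.insertion_code) for e in table]
        index = {key: i for i, key in enumerate(order)}
        keys = set()
        for seg in self.segments:
            a = index[(seg.chain_id, seg.start, seg.start_icode)]
            b = index[(seg.chain_id, seg.end, seg.end_icode)]
            keys.update(order[a:b + 1])
        return frozenset(keys)


@dataclass(frozen=True)
class Segmentation:
    """An ordered domain decomposition plus the unassigned residues."""

    domains: tuple[Domain, ...]
    unassigned: frozenset[int] = frozenset()
    params_used: dict | None = None

    @property
    def n_domains(self) -> int:
        return len(self.domains)


def _runs(indices: Sequence[int]) -> list[tuple[int, int]]:
    """Maximal runs of consecutive integers, as (first, last) inclusive."""
    runs = []
    start = prev = indices[0]
    for i in indices[1:]:
        if i == prev + 1:
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    return runs


def clusters_to_segmentation(assignment: ClusterAssignment,
                             residues: ResidueTable | None = None,
                             min_size: int = DEFAULT_MIN_SIZE,
                             exclude: frozenset[int] = frozenset()) -> Segmentation:
    """Turn cluster labels into domains of residue intervals.

    Maximal runs of consecutive residues sharing a label become segments;
    all segments of a cluster form one (possibly discontinuous) domain.
    Clusters with fewer than ``min_size`` residues are moved wholly to
    unassigned. Domains are numbered in order of their first residue.

    ``exclude`` lists residue indices to send straight to unassigned (e.g.
    residues with no confident partner in the network); cluster sizes are
    counted after their removal.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    labels = assignment.labels
    n = len(labels)
    if residues is not None and len(residues) != n:
        raise ReconciliationError(
            f"assignment covers {n} residues but table has {len(residues)}")
    table = residues if residues is not None else default_residue_table(n)

    by_label: dict[int, list[int]] = {}
    for i, lab in enumerate(labels):
        if i not in exclude:
            by_label.setdefault(lab, []).append(i)

    unassigned: set[int] = set(exclude)
    domains: list[Domain] = []
    for lab, idxs in by_label.items():
        if len(idxs) < min_size:
            unassigned.update(idxs)
            continue
        segments = []
        for a, b in _runs(idxs):
            # split runs that straddle a chain boundary
            start = a
            for i in range(a, b + 1):
                if i > start and table[i].chain_id != table[start].chain_id:
                    segments.append(_make_segment(table, start, i - 1))
                    start = i
            segments.append(_make_segment(table, start, b))
        segments.sort(key=lambda s: (s.chain_id, s.start, s.start_icode))
        domains.append(Domain(tuple(segments), residue_count=len(idxs)))

    domains.sort(key=lambda d: (d.segments[0].chain_id, d.segments[0].start,
                                d.segments[0].start_icode))
    return Segmentation(tuple(domains), frozenset(unassigned))


def _make_segment(table: ResidueTable, a: int, b: int) -> Segment:
    ea, eb = table[a], table[b]
    return Segment(ea.chain_id, ea.author_seq_id, eb.author_seq_id,
                   ea.insertion_code, eb.insertion_code)


def to_chopping_string(seg: Segmentation) -> str:
    """Serialize a segmentation to the canonical chopping grammar.

    The chain prefix ``C:`` is emitted only when more than one chain appears.
    An all-unassigned segmentation serializes to the empty string.
    """
    chains = {s.chain_id for d in seg.domains for s in d.segments}
    multi = len(chains) > 1
    parts = []
    for dom in seg.domains:
        toks = []
        for s in dom.segments:
            rng = f"{s.start}{s.start_icode}-{s.end}{s.end_icode}"
            toks.append(f"{s.chain_id}:{rng}" if multi and s.chain_id else rng)
        parts.append("_".join(toks))
    return ",".join(parts)


_RANGE_RE = re.compile(r"^(?:(?P<chain>[A-Za-z0-9]+):)?"
                       r"(?P<start>-?\d+)(?P<sic>[A-Za-z]?)"
                       r"-(?P<end>-?\d+)(?P<eic>[A-Za-z]?)$")


def parse_chopping_string(text: str) -> Segmentation:
    """Parse a chopping string back into a Segmentation (inverse of
    :func:`to_chopping_string` on canonical strings)."""
    text = text.strip()
    if not text:
        return Segmentation(())
    domains = []
    for dom_tok in text.split(","):
        segments = []
        count = 0
        for seg_tok in dom_tok.split("_"):
            m = _RANGE_RE.match(seg_tok.strip())
            if not m:
                raise ChoppingParseError(f"malformed segment token {seg_tok!r}")
            start, end = int(m["start"]), int(m["end"])
            if start > end:
                raise ChoppingParseError(
                    f"segment {seg_tok!r} has start > end")
            segments.append(Segment(m["chain"] or "", start, end,
                                    m["sic"], m["eic"]))
            count += end - start + 1
        segments.sort(key=lambda s: (s.chain_id, s.start, s.start_icode))
        domains.append(Domain(tuple(segments), residue_count=count))
    domains = tuple(sorted(domains, key=lambda d: (d.segments[0].chain_id,
                                                   d.segments[0].start)))
    return Segmentation(domains)


def annotate_structure(structure: Source, seg: Segmentation,
                       format: str = "auto", out_format: str | None = None) -> bytes:
    """Write the domain index of each residue into the B-factor column.

    Unassigned residues get -1; domain indices are 1-based. Everything else
    in the structure is preserved, so the result colours by domain in any
    molecular viewer.
    """
    raw = _read_bytes(structure)
    st = _load_structure(raw, format)
    residues = list(_polymer_residues(st))

    n = sum(d.residue_count for d in seg.domains) + len(seg.unassigned)
    if len(residues) != n:
        raise ReconciliationError(
            f"structure has {len(residues)} polymer residues, segmentation covers {n}")

    # map file-order residue index -> domain index (1-based) or -1
    label = [-1] * len(residues)
    seg_chains = {s.chain_id for d in seg.domains for s in d.segments}
    if seg_chains <= {""}:
        # matrix-only segmentation: 1..n numbering, resolved by file order
        table = default_residue_table(len(residues))
    else:
        table = ResidueTable(tuple(
            ResidueEntry(cid, r.seqid.num, r.seqid.icode.strip())
            for cid, r in residues))
    key_to_idx = {(e.chain_id, e.author_seq_id, e.insertion_code): i
                  for i, e in enumerate(table)}
    for d_idx, dom in enumerate(seg.domains, start=1):
        for key in dom.residues(table):
            label[key_to_idx[key]] = d_idx

    for (cid, res), lab in zip(residues, label):
        for atom in res:
            atom.b_iso = float(lab)

    if out_format is None:
        text = raw.decode("utf-8", errors="replace").lstrip()
        out_format = "mmcif" if text.startswith("data_") or text.startswith("#") else "pdb"
    if out_format == "pdb":
        return st.make_pdb_string().encode()
    return st.make_mmcif_document().as_string().encode()


def segmentation_table(seg: Segmentation) -> str:
    """TSV with columns domain_index, n_segments, chopping, n_residues."""
    buf = io.StringIO()
    writer = csv.writer(buf, delimiter="\t", lineterminator="\n")
    writer.writerow(["domain_index", "n_segments", "chopping", "n_residues"])
    for i, dom in enumerate(seg.domains, start=1):
        writer.writerow([i, len(dom.segments),
                         to_chopping_string(Segmentation((dom,))),
                         dom.residue_count])
    return buf.getvalue()


def residue_csv(seg: Segmentation, residues: ResidueTable) -> str:
    """Per-residue CSV: residue (1-based file order), chain, author number,
    pLDDT, domain index (-1 = unassigned)."""
    label = {}
    for d_idx, dom in enumerate(seg.domains, start=1):
        for key in dom.residues(residues):
            label[key] = d_idx
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["residue", "chain", "author_number", "plddt", "domain"])
    for i, e in enumerate(residues, start=1):
        key = (e.chain_id, e.author_seq_id, e.insertion_code)
        writer.writerow([i, e.chain_id, f"{e.author_seq_id}{e.insertion_code}",
                         e.plddt, label.get(key, -1)])
    return buf.getvalue()
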