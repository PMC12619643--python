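"""Synthetic PAE matrices with planted domain structure.

Real AlphaFold PAE matrices show low error between residue pairs inside a
well-packed domain, high error between independently placed domains, and a
band of uniformly high error along rows/columns of disordered linkers.
The generator plants exactly those block statistics:

* intra-domain entries uniform on ``intra_range`` (default 1-4 A),
* inter-domain entries uniform on ``inter_range`` (default 22-30 A),
* linker rows AND columns drawn from ``inter_range`` regardless of block,
* independent uniform jitter up to ``asymmetry_jitter`` on (i, j) vs (j, i)
  to mimic the asymmetry of raw PAE,
* values clamped to [0, 31.75] (the AlphaFold DB declared maximum), zero
  diagonal.

Because the ranges are disjoint (uniform, bounded support), every intra
pair has strictly lower PAE than every inter pair, so the monotone logistic
transform preserves the planted separability exactly — the fixture is
recoverable by construction, which is what a segmentation correctness test
needs. Distance-dependent PAE decay and other correlations of real
predictions are deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GenerationError
from .pae_io import AFDB_MAX_PAE, PaeMatrix
from .segmentation import Domain, Segment, Segmentation


@dataclass(frozen=True)
class PlantedSpec:
    """Specification of a planted-domain PAE fixture.

    linker_positions are (start, length) pairs, 0-based over the
    concatenated residue range; linker residues are carved out of the
    planted blocks and are expected to end up unassigned.
    """

    domain_lengths: tuple[int, ...]
    intra_range: tuple[float, float] = (1.0, 4.0)
    inter_range: tuple[float, float] = (22.0, 30.0)
    linker_positions: tuple[tuple[int, int], ...] = ()
    asymmetry_jitter: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "domain_lengths", tuple(int(x) for x in self.domain_lengths))
        object.__setattr__(self, "linker_positions",
                           tuple((int(a), int(b)) for a, b in self.linker_positions))
        if not self.domain_lengths or any(x <= 0 for x in self.domain_lengths):
            raise GenerationError("domain_lengths must be positive integers")
        for lo, hi in (self.intra_range, self.inter_range):
            if not (0 <= lo < hi <= AFDB_MAX_PAE):
                raise GenerationError(f"range ({lo}, {hi}) outside [0, {AFDB_MAX_PAE}]")
        if self.intra_range[1] >= self.inter_range[0]:
            raise GenerationError("intra_range must lie strictly below inter_range")
        n = self.n
        spans = []
        for start, length in self.linker_positions:
            if length <= 0 or start < 0 or start + length > n:
                raise GenerationError(f"linker ({start}, {length}) outside 0..{n}")
            spans.append(range(start, start + length))
        covered = [i for s in spans for i in s]
        if len(covered) != len(set(covered)):
            raise GenerationError("linkers overlap")

    @property
    def n(self) -> int:
        return sum(self.domain_lengths)

    @property
    def linker_indices(self) -> frozenset[int]:
        return frozenset(i for start, length in self.linker_positions
                         for i in range(start, start + length))


def _block_ids(lengths: tuple[int, ...]) -> np.ndarray:
    return np.repeat(np.arange(len(lengths)), lengths)


def _truth_from_blocks(block_of: np.ndarray, linkers: frozenset[int]) -> Segmentation:
    """Ground truth: each block is a domain minus any carved-out linker
    residues; linker residues are unassigned."""
    domains = []
    for b in range(block_of.max() + 1):
        idxs = [i for i in np.flatnonzero(block_of == b) if i not in linkers]
        if not idxs:
            continue
        segments = []
        start = prev = idxs[0]
        for i in idxs[1:]:
            if i != prev + 1:
                segments.append(Segment("", start + 1, prev + 1))
                start = i
            prev = i
        segments.append(Segment("", start + 1, prev + 1))
        domains.append(Domain(tuple(segments), residue_count=len(idxs)))
    domains.sort(key=lambda d: d.segments[0].start)
    return Segmentation(tuple(domains), frozenset(linkers))


def _assemble(base: np.ndarray, spec: PlantedSpec, rng: np.random.Generator) -> PaeMatrix:
    n = spec.n
    pae = base.copy()
    if spec.linker_indices:
        link = sorted(spec.linker_indices)
        pae[link, :] = rng.uniform(*spec.inter_range, size=(len(link), n))
        pae[:, link] = rng.uniform(*spec.inter_range, size=(n, len(link)))
    jitter = rng.uniform(0.0, spec.asymmetry_jitter, size=(n, n))
    pae = np.clip(pae + jitter, 0.0, AFDB_MAX_PAE)
    np.fill_diagonal(pae, 0.0)
    return PaeMatrix(pae, dialect="afdb", max_pae=AFDB_MAX_PAE)


def _base_matrix(rng: np.random.Generator, n: int, same_fine: np.ndarray,
                 same_coarse: np.ndarray, intra: tuple[float, float],
                 mid: tuple[float, float] | None,
                 inter: tuple[float, float]) -> np.ndarray:
    """Block matrix draw; the mid layer is drawn only when a split exists,
    so a trivial hierarchy consumes the same random stream as a flat one."""
    base = rng.uniform(*intra, size=(n, n))
    cross_mid = same_coarse & ~same_fine
    if cross_mid.any():
        assert mid is not None
        base = np.where(cross_mid, rng.uniform(*mid, size=(n, n)), base)
    return np.where(~same_coarse, rng.uniform(*inter, size=(n, n)), base)


def generate(spec: PlantedSpec) -> tuple[PaeMatrix, Segmentation]:
    """Generate a planted-domain PAE matrix and its ground-truth segmentation.

    Fully reproducible from ``spec.seed``: the same spec yields bit-identical
    matrices.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    block_of = _block_ids(spec.domain_lengths)
    same_block = block_of[:, None] == block_of[None, :]
    base = _base_matrix(rng, n, same_block, same_block,
                        spec.intra_range, None, spec.inter_range)
    pae = _assemble(base, spec, rng)
    truth = _truth_from_blocks(block_of, spec.linker_indices)
    return pae, truth


def generate_hierarchical(spec: PlantedSpec,
                          sub_split: tuple[tuple[float, ...], ...],
                          mid_range: tuple[float, float] = (10.0, 14.0),
                          ) -> tuple[PaeMatrix, Segmentation, Segmentation]:
    """Two-level fixture: domains split into sub-blocks at intermediate PAE.

    ``sub_split[d]`` gives the length fractions of domain d's sub-blocks
    (must sum to 1). Cross-sub-block pairs within a domain are drawn from
    ``mid_range``, which must sit strictly between ``intra_range`` and
    ``inter_range``; a low clustering resolution then recovers the coarse
    partition and a high resolution the fine one.

    Returns (matrix, coarse ground truth, fine ground truth).
    """
    if len(sub_split) != len(spec.domain_lengths):
        raise GenerationError("sub_split must list fractions per domain")
    if not (spec.intra_range[1] < mid_range[0] < mid_range[1] < spec.inter_range[0]):
        raise GenerationError("mid_range must lie strictly between intra and inter ranges")

    fine_lengths: list[int] = []
    for length, fracs in zip(spec.domain_lengths, sub_split):
        if abs(sum(fracs) - 1.0) > 1e-9 or any(f <= 0 for f in fracs):
            raise GenerationError(f"fractions {fracs} must be positive and sum to 1")
        subs = [int(round(length * f)) for f in fracs]
        subs[-1] = length - sum(subs[:-1])
        if any(s <= 0 for s in subs):
            raise GenerationError(f"fractions {fracs} give an empty sub-block")
        fine_lengths.extend(subs)

    rng = np.random.default_rng(spec.seed)
    n = spec.n
    coarse_of = _block_ids(spec.domain_lengths)
    fine_of = _block_ids(tuple(fine_lengths))
    same_coarse = coarse_of[:, None] == coarse_of[None, :]
    same_fine = fine_of[:, None] == fine_of[None, :]
    base = _base_matrix(rng, n, same_fine, same_coarse,
                        spec.intra_range, mid_range, spec.inter_range)
    pae = _assemble(base, spec, rng)
    coarse = _truth_from_blocks(coarse_of, spec.linker_indices)
    fine = _truth_from_blocks(fine_of, spec.linker_indices)
    return pae, coarse, fine
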