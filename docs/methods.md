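# Methods

## Model

A predicted structure's PAE matrix is an n×n, generally asymmetric,
non-negative matrix of expected position errors in Å (AlphaFold DB caps it
at 31.75 Å). The segmentation model treats each residue as a node of a
fully connected weighted graph. Because the raw matrix is asymmetric while
an undirected edge needs a single value, PAE<sub>ij</sub> and
PAE<sub>ji</sub> are averaged before weighting (the arithmetic mean is the
least aggressive symmetrization; taking the minimum would systematically
inflate confidence). The edge weight is the logistic

    w_ij = 1 / (1 + exp(PAE_ij − T))

with contrast threshold `T` in Å (default 2). Useful properties, all
asserted in the test suite:

* `w = 0.5` exactly at `PAE = T`;
* strictly decreasing in PAE, so the weight ranking is the exact reverse
  of the symmetrized-PAE ranking (the transform is monotone, not
  information-destroying);
* translation invariant: raising `T` by δ equals subtracting δ from every
  PAE value;
* computed via a branch-stable logistic (`scipy.special.expit`), so PAE up
  to 10⁴ yields a finite positive weight, never NaN or overflow. Weights
  are clamped to the smallest normal float from below so the graph stays
  strictly positive and fully connected.

The graph is partitioned with the Leiden algorithm (`leidenalg`), and the
partition is mapped back to sequence intervals: maximal runs of
consecutive same-cluster residues become segments, all segments of a
cluster form one (possibly discontinuous) domain.

## Quality function: modularity by default, CPM as an option

The clustering objective is genuinely a free choice in this design, and
the two candidates behave very differently on logistic weights:

* **CPM**, Σ_c (W_c − γ·n_c(n_c−1)/2), reads the resolution γ as an
  *absolute* per-pair weight threshold. Since weights live in (0, 1), a
  cluster only survives where the mean pairwise weight exceeds γ. That is
  beautifully interpretable, but it hard-couples the useful γ range to the
  PAE scale of the input: with intra-domain PAE around 1–4 Å and T = 2,
  weights sit near 0.1–0.6, and γ = 0.7 dissolves everything into
  singletons; no γ above 1 can ever retain a cluster.
* **Weighted modularity** (null term scaled by γ) compares intra-cluster
  weight against a degree-matched random expectation, so it adapts to the
  absolute weight level. The recommended resolution 0.7 — and the whole
  0.4–0.8 exploration range — then works across inputs whose confidence
  scales differ.

Modularity is therefore the default; CPM remains selectable
(`objective="cpm"`) and is the objective used in the exhaustive-oracle
tests, where the global optimum over all set partitions of tiny graphs is
enumerable (Bell(10) = 115,975 partitions) and Leiden must match it.

The quality reported with every assignment is recomputed from the returned
labels by an explicit summation, independent of the optimizer's internal
value — a cheap end-to-end consistency check.

## Determinism and canonical labels

All Leiden randomness flows from a single integer seed (default 0) passed
to `leidenalg`; identical inputs and seed give identical partitions, which
the CLI tests assert at byte level on the output files. Cluster ids are
canonicalized by first occurrence (cluster 0 contains residue 0, etc.) so
partitions are directly comparable across runs, implementations and node
permutations. Within-algorithm tie-breaking is delegated to the seeded
optimizer rather than re-implemented, since only reproducibility — not a
specific tie order — is observable in the output.

## Unassigned residues

Two filters move residues to "unassigned" instead of a domain:

1. **Minimum domain size** (default 10 residues, user-overridable):
   clusters smaller than this are structurally meaningless fragments
   (termini, crumbs of disordered regions). Filtered clusters are not
   merged into neighbours — any merge rule would be arbitrary — and
   increasing `min_size` can only reduce the domain count (asserted as a
   property test).
2. **No confident partner**: a residue whose minimum symmetrized PAE to
   *every* other residue exceeds T (equivalently, whose best edge weight
   is below the logistic midpoint 0.5) carries no positive evidence for
   membership in any domain. Without this rule a uniformly high-PAE band —
   the signature of a disordered linker — gets absorbed into whichever
   neighbouring domain the optimizer drifts it into, because under
   modularity the (tiny) attachment weight always beats the (tinier) null
   term; the absorption is structural, not noise. The rule introduces no
   new tunable: it is derived from T, and it is the package's answer to
   the open question of pre-report filtering. Its one visible cost is that
   an occasional ordinary residue whose best PAE sits marginally above T
   is also dropped — defensible, since at that contrast setting the model
   genuinely expresses no confidence about it.

## Synthetic fixtures

The generator plants exactly the block statistics the method exploits:
intra-domain PAE uniform on (1, 4) Å, inter-domain on (22, 30) Å,
disordered linkers as full rows *and* columns at inter-domain level,
independent uniform jitter up to 1 Å between (i,j) and (j,i) to mimic PAE
asymmetry, values capped at 31.75 Å, zero diagonal. Uniform (bounded)
noise rather than Gaussian guarantees exact separability: every intra pair
beats every inter pair through the monotone transform, for any T. The
hierarchical variant inserts an intermediate level (default 10–14 Å)
between sub-domains of a domain, so a resolution sweep shows the coarse →
fine transition.

What the fixtures deliberately do **not** emulate: distance-dependent PAE
decay, correlated errors, partial-confidence interfaces, or the low PAE
real disordered residues still show to their immediate sequence
neighbours. Passing the planted-recovery tests therefore demonstrates that
the pipeline is correct and well-calibrated for block-structured
confidence signals, not that any particular accuracy will be reached on
real proteins.

For the multi-resolution demonstration the contrast threshold is set to
12 Å — the centre of the intermediate PAE level — because at T = 2 the
logistic saturates for everything above ~6 Å and the intermediate level
becomes numerically invisible (weights ~5·10⁻⁵). That is the intended use
of the threshold: centre the soft cut-off on the error scale being probed.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `threshold` (T) | 2 | Å | logistic midpoint; soft confident/unconfident cut-off; explore 0–4 |
| `resolution` | 0.7 | – | Leiden granularity; explore 0.4–0.8; higher ⇒ more, smaller domains |
| `objective` | modularity | – | quality function; `cpm` for absolute-weight-threshold semantics |
| `min_size` | 10 | residues | smallest cluster reported as a domain |
| `n_iterations` | 10 | – | Leiden refinement cap; dense graphs stabilize far earlier |
| `seed` | 0 | – | single source of clustering randomness |

## IoU evaluation

Predicted and reference domains are residue sets (unassigned residues
belong to no set). Pairwise IoU = |A∩B|/|A∪B|; domains are matched
one-to-one by optimal assignment (Hungarian algorithm via
`scipy.optimize.linear_sum_assignment`), and the mean IoU divides the
matched sum by max(n_pred, n_ref), so surplus domains on either side count
as zero — over- and under-segmentation are penalized symmetrically. The
normalization is a documented choice isolated behind one function;
averaging over matched pairs only would ignore domain-count disagreement
entirely. Equivalence with brute-force permutation search is asserted for
up to 6×6 domain sets.

## Numerical and format choices

* Pair-list PAE JSON may be sparse; missing pairs are imputed with the
  declared maximum PAE (or the largest observed value), i.e. treated as
  unconfident rather than confident.
* The PAE diagonal is stored as found in the file but ignored by the graph
  (zero weight, no self-loops); the modularity null term's diagonal
  contribution is constant across partitions and does not affect optima.
* Chopping grammar: `-` ranges, `_` joins segments of a discontinuous
  domain, `,` separates domains, `C:` chain prefix only for multi-chain
  output; residues with insertion codes are addressed as `52A` and ranges
  resolve by file order, not arithmetic.
* Multimer support concatenates chains in file order, matching the joint
  PAE matrix of multimer predictions; sequence runs never cross a chain
  boundary.
* Problem sizes in the tests and the acceptance script (300-residue flat
  fixtures, 200-residue hierarchical fixture, 20 and 10 generator seeds,
  10-node exhaustive enumeration) were chosen as the smallest sizes at
  which the planted structure is unambiguous and domain counts are
  realistic.

## Known limitations

* Segmentation quality inherits every pathology of the input PAE:
  overconfident predictions (training-set leakage) need a higher T, and
  the tool cannot detect that case automatically.
* No benchmark against curated domain databases ships with the package;
  the IoU module implements the statistic, not the benchmark.
* AlphaFold3 full-data CIF confidence records are not parsed; only the
  three JSON dialects listed above.
* The Leiden stage is re-run per resolution in a sweep; no hierarchical
  dendrogram is exposed.
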