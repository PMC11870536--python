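# Methods

This note documents the models, numerical choices and synthetic-data
design behind `pathnet`, in the spirit of a statistical-software methods
appendix.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Model and assumptions

### Over-representation test

Enrichment of a gene list in an ontology term is assessed with the
right-tailed Fisher's exact test, i.e. the hypergeometric upper tail
P(X ≥ k) for X ~ Hypergeom(N, K, n):

- **N** — universe size.  By default the ontology's annotated gene set
  (every gene annotated to at least one term after propagation).  When a
  dataset carries an experimental background — the genes that were
  actually tested for significance, supplied in a `*_bgGenes` file — the
  universe is the intersection of background and annotated genes.  This
  is the correct conditioning: genes never tested cannot count as
  "not drawn".
- **K** — term genes within the universe; **n** — analyzed dataset genes
  within the universe; **k** — their overlap.
- Terms with k = 0 are omitted from results rather than reported with
  p = 1; this matches over-representation convention and keeps outputs
  compact.

Gene identity is by symbol, uppercased and whitespace-stripped.  No
cross-identifier mapping is attempted; callers must supply symbols in a
single nomenclature.

No multiple-testing correction enters the significance call.
Significance is deliberately the two-cutoff rule described next, which
is rank-bounded and therefore self-limiting; a Benjamini–Hochberg
adjusted column (`p_bh`, via `scipy.stats.false_discovery_control`) is
emitted in result tables as supplementary information only.

### Per-level cutoffs and ranking

Hierarchical ontologies with explicit levels (1 = most general) are
ranked per level: within each level results are ordered by ascending p
and assigned competition ranks — ties share the smallest applicable
rank, so p-values (.001, .001, .01) rank (1, 1, 3).  A term is
significant iff p ≤ max_p *and* rank ≤ max_rank for its level; defaults
are max_p = 0.05, max_rank = 5, overridable per level
(`LevelCutoffs.from_lists([...], [...])`, e.g. ranks 5/5/10/5 for a
4-level ontology).  Tie order in reported lists is made deterministic by
a lexicographic term-id tiebreak.  Level-less ontologies (GO) use the
global cutoffs as a single pseudo-level.

### Dynamic enrichment

The interaction network supplies weighted, undirected functional
relations between same-level SCPs.  For a chosen top-percentage x, the
ceil(x/100 · |E|) highest-weight edges are retained, plus any edges tied
with the weakest retained weight (deterministic, order-independent).
Within each level, every 2- or 3-subset of SCPs such that

1. each member's gene set intersects the analyzed gene set, and
2. the subset's induced subgraph in the retained network is connected
   (for triples: at least two of the three possible edges)

is merged into a dataset-selective term whose gene set is the union of
the members.  Merged terms are Fisher-tested against the same universe
and ranked *together with* the singleton terms of that level under the
(separately specifiable) dynamic cutoffs.  Merged-term ids are
deterministic: `MERGED::<id1>+<id2>[+<id3>]` with members sorted.

Each significant merged result of m members then contributes
−log₁₀(p)/m to every member; a singleton's own −log₁₀(p) counts iff the
singleton itself is significant.  Per SCP the contributions are summed
(with `math.fsum`, so the total mass equals the summed −log₁₀(p) of the
significant results exactly) and the contributing merged ids recorded.
Two consequences worth knowing:

- With an empty retained network, dynamic analysis reduces to standard
  analysis exactly (field-by-field, given equal cutoffs).
- A singleton that is *not* significant in the combined ranking reports
  a split value of 0 plus any merged shares; its own p-value, counts and
  rank are still reported.

Enumeration is quadratic/cubic in the number of same-level SCPs with
dataset genes.  This is intended for MBCO-scale ontologies (tens of SCPs
per level); it is not suitable for running dynamic analysis over all of
GO, which is also biologically questionable given GO's within-level
redundancy.

### Network assembly

For one integration group and one analysis type, the node set is the
union of the datasets' significant SCPs, each a pie chart with one slice
per predicting dataset (slice value −log₁₀ p, slice order following the
datasets' display order).  Edge kinds: hierarchical (parent → child,
directed), functional (top-percent interactions, undirected), regulatory
(GO "regulates"-family, directed, off by default), gene membership
(SCP → gene child nodes, dashed).  Unpredicted ancestors are inserted
either as *intermediates only* — terms lying on a directed
ancestor-descendant path whose endpoints are both predicted, computed as
(descendants of predicted) ∩ (ancestors of predicted) — or as the full
ancestor closure.  Inserted ancestors are visually distinct: fixed small
area (reference diameter / 4), gray fill, no slices.

Node areas: in *significance* mode area ∝ summed slice values with
proportional slice angles; *dataset count*, *color count* and *uniform*
modes use equal angles.  The proportionality constant is fixed by giving
the largest node in the scaling context the reference diameter (80
drawing units); the context is either the single network or, for
cross-network comparability, a shared maximum passed in by the caller
(`max_scaling_metric`).  Label sizes interpolate linearly between a
minimum and maximum (8–24 pt default) over the node-area range, with all
labels at the minimum when areas are equal.

### graphml dialect

Files target the yEd extension namespace so they open directly in the
yEd editor.  Multi-slice nodes are embedded-SVG pie charts (yEd has no
native pie node); single-slice, ancestor and gene nodes are plain
ellipses with the appropriate fill.  Hierarchical/regulatory edges carry
target arrows; functional edges none; gene-membership edges are dashed.
Alongside the styling, each node carries machine-readable `data` fields
(kind, area, total value, JSON slice list), which makes the emitted file
a lossless serialization — `read_graphml_summary` restores the graph for
round-trip verification.  Layout coordinates are intentionally absent;
arranging nodes is the editor's job.

## Ontology handling

- OBO parsing is delegated to `obonet`; `is_a` and `part_of` become
  parent-child edges, "regulates"-family relationships are stored
  separately, obsolete terms are dropped.  Acyclicity is verified and a
  violating cycle reported.
- GAF 2.x rows must have 17 columns (malformed rows fail with a line
  number); rows with a NOT qualifier are skipped, as are rows for terms
  absent from the ontology (counted and logged).  All evidence codes are
  accepted, including IEA.
- The flat dialect carries explicit levels; every child must sit exactly
  one level below its parent, and multiple parents are allowed (DAG
  semantics, matching GO).
- Annotation propagation populates each term with the union of its
  descendants' genes (topological order; idempotent).
- Size filtering removes terms outside [min, max] genes and re-closes
  the hierarchy by connecting each survivor to its nearest surviving
  ancestors (transitive reduction of the induced ancestor relation).
  Re-closure keeps filtered DAGs connected where the original was — a
  deliberate choice so that ancestor insertion still works after
  filtering.
- User-defined merged SCPs (`define_custom_scp`) take the union of their
  members' genes, adopt the members as children, and sit one level above
  the shallowest member (floored at level 1).

## Numerical choices

- **Fisher tail.**  The leading term P(X = k) is computed from exact
  integer binomial coefficients (`math.comb`), whose float conversion is
  correctly rounded; subsequent terms follow the hypergeometric ratio
  recurrence P(X = j+1)/P(X = j) = (K−j)(n−j) / ((j+1)(N−K−n+j+1)),
  whose factors are exact small integers.  This keeps the relative error
  near machine precision (observed ≲ 1e-13 against exact rational
  arithmetic) for universes up to at least 10⁴ genes — an order of
  magnitude tighter than a pure log-gamma accumulation, whose absolute
  log error grows with N.  Only when the leading term underflows the
  double range does the implementation fall back to log-space
  accumulation (log-gamma + logsumexp); below the smallest subnormal,
  −log₁₀(p) is clamped at ≈ 323.3.
- **−log₁₀ p** is computed from the rounded p-value, so the reported
  pair is internally consistent.
- **Splitting** uses `math.fsum` for each per-SCP sum, making the mass
  conservation identity exact rather than approximate.
- **Determinism.**  All tie-breaks are lexicographic; palette colors are
  assigned over sorted group keys; merged ids and dump file names are
  deterministic.  Re-importing an input dump reproduces enrichment
  tables byte-identically.

## Synthetic data

The generator (`pathnet.fixtures`) emulates the *shape* of a small
MBCO-style study, not its biology:

- A complete 3-level, branching-factor-3 ontology: 1 root, 3 branches, 9
  leaf SCPs.  Each leaf carries a disjoint 40-gene block plus a 5-gene
  overlap into the next leaf (mimicking shared annotations); all
  remaining genes attach to the root, so the annotated universe is
  exactly 2,000 genes.
- Datasets are built as: 80 % of one planted SCP's genes (sampled
  without replacement), plus each other universe gene independently with
  probability 0.05, with significance-like values below the default 0.05
  cutoff.  These defaults — 80 % planted fraction, 5 % noise, 2,000-gene
  universe — are the benchmark conditions the recovery tests and the
  acceptance script run under (100 replicates each).
- Split-signal pairs place 25 % of each member's genes into the dataset
  while guaranteeing the pair a top-decile interaction weight, so the
  merged pair — not either member alone — carries the strongest
  evidence.  This is the construction that makes the dynamic-enrichment
  advantage testable.
- Interaction edges are sampled within-level at density 0.3 with
  uniform weights on [0, 1).
- All sampling flows through one seeded `numpy` generator per artifact;
  fixed seed ⇒ byte-identical files.

What the generator does *not* emulate: realistic expression noise,
correlated gene membership across terms, GO's topology (depth,
fan-in/out distributions), or symbol aliasing.  Passing recovery tests
therefore demonstrates the statistical machinery works as specified
under controlled conditions — not that any particular biological claim
holds on real data.

## Problem sizes in tests

The test suite verifies the Fisher tail exhaustively for all valid count
tuples with N ≤ 60 (≈ 6 × 10⁵ tuples) plus 500 random tuples with
N ≤ 10⁴ against exact rational arithmetic; DAG operations against
brute-force oracles on 100 random DAGs of up to 60 terms; merged-SCP
enumeration against subset brute force on graphs of up to 12 same-level
terms; and recovery rates over 100 seeded replicates of the synthetic
study.  These sizes give tight oracles while keeping the full suite
under a minute of compute.

## Known limitations

- Dynamic enrichment merges only within a level and only up to triples,
  by design.
- The background check is fail-soft: dataset genes outside the universe
  are dropped (with a logged count), not rejected — background files in
  the wild are routinely incomplete.
- A dataset belongs to exactly one integration group; two files defining
  the same dataset name are an error.
- SCP-selection groups mark their results significant so every
  downstream consumer (tables, networks) includes them; the original
  flags are not preserved through that path.
- `keep_top_n` interprets "top" as smallest value (significance
  semantics); a flag flips it for effect-size-like columns.
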