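# Methods

## Scope and model

The package treats protein function analysis as three linked views of the
same protein set: a phylogeny, per-protein domain architectures, and the
genomic neighborhoods of the encoding genes. The assumptions are the usual
ones for prokaryotic comparative genomics: genes are annotated CDS features
on linear or circular replicons, each query protein maps to exactly one
gene, and co-transcription can be approximated from intergenic distance
alone.

Coordinates are 0-based half-open internally; every external format keeps
its native convention (GFF3 and the JSON export are 1-based inclusive,
protein features are 1-based inclusive throughout). This conversion happens
only at the format boundary, in `io.py`.

## Domain architectures

Raw hits arrive as HMMER3 `domtblout` rows (envelope coordinates define the
feature extent; the per-domain independent E-value and bit score are the
hit's statistics) or as a generic TSV. Two steps produce an architecture:

1. **E-value filter.** Domain hits with independent E-value above
   `evalue_max` (default 0.01) are dropped. Transmembrane and
   low-complexity features have no comparable E-value and bypass the
   filter. The default is a conventional reporting cutoff for profile
   searches; it is deliberately permissive because the overlap-resolution
   step removes spurious secondary hits anyway.
2. **Overlap resolution.** Hits are taken greedily in order of descending
   bit score (ties: smaller E-value, then smaller start, then accession); a
   hit is accepted iff its overlap with every accepted hit is at most
   `overlap_fraction_max` (default 0.2) of the shorter of the two. Greedy
   max-score-first matches how architecture drawings are usually pruned and
   is verified against an exhaustive best-subset search on small cases in
   the tests.

Identifier extraction from tree leaf names accepts four delimiters
(underscore, space, slash, vertical bar). Because RefSeq accessions contain
an underscore, a leading versioned accession (`XX_…​.N`) is recognised first
and kept intact; then the name is split at the first space/`|`/`/`; the
underscore is the last resort. The function is total and idempotent
(property-tested).

## Redundancy reduction

Greedy incremental clustering, longest sequence first: a sequence joins the
first representative with global-alignment identity ≥ the user threshold,
else founds a new cluster. Identity is matches / alignment length under
match = 1, mismatch = 0, linear gap −1 (Needleman–Wunsch; computed with
biopython's `PairwiseAligner` and cross-checked against an independent DP in
the tests). This is a CD-HIT-like strategy with an exact alignment instead
of a word filter — adequate at the scale this library targets (hundreds of
sequences), quadratic in the worst case.

## Tree construction

The builtin backend is intentionally alignment-free so the package runs
with no external binaries:

- **k-mer distance** `d(i,j) = 1 − |K_i ∩ K_j| / min(|K_i|, |K_j|)` over
  k-mer sets (default k = 3). The min-normalisation keeps a fragment at
  distance ≈ 0 from its full-length parent, which suits two-area analyses.
- **Neighbor joining** with the Saitou–Nei Q-criterion. Determinism is
  guaranteed by a total tie-break: among Q-minimal pairs the
  lexicographically smallest pair of labels wins, an internal node being
  labelled by the smallest leaf it contains. Negative branch length
  estimates (possible on non-additive inputs) are clamped to zero with the
  deficit moved to the sibling branch, preserving the joined pair's path
  length. The last three nodes join a trifurcating root via the three-point
  formulas, so the output is the standard unrooted NJ tree.

On additive matrices NJ provably recovers the generating topology; the test
suite checks this on matrices read off random trees (Robinson–Foulds
distance 0 via scikit-bio) and compares the implementation node-for-node
(topology plus all tip-to-tip path lengths) with a brute-force
recompute-everything NJ written independently in the tests.

External aligner/tree-builder adapters run any shell command template with
`{input}`/`{output}` placeholders and re-parse the result with the package's
own readers; trees from the builtin backend are labelled `builtin_nj` in
metadata so they are never mistaken for alignment-based output. The builtin
"aligner" is an identity passthrough: pre-aligned input is used as-is, and
unaligned input is carried through unaligned (flagged so) while the tree
comes from k-mer distances — a real MSA requires wiring an external
aligner.

## Neighborhoods, clusters, operons

- **Window.** `window` (default 5) counts genes per side of the query. The
  window truncates at linear replicon ends (recorded per side) and wraps on
  circular replicons (recorded as a wrap flag; coordinates stay unwrapped).
- **Clustering.** A gene's signature is the *set* of domain accessions of
  its protein (duplicates collapse; TM/low-complexity excluded). Two genes
  are compatible when their signatures differ by at most `nonshared_max`
  elements (symmetric difference); clusters are connected components of
  this relation. Compatibility is not transitive for k > 0, so the
  component (single-linkage) definition is what makes the partition well
  defined; at k = 0 it degenerates to grouping by identical non-empty sets,
  which is checked against a hash-grouping oracle. Two empty signatures are
  *never* compatible — "shared domains" is vacuous for domain-less genes —
  so such genes stay unclustered and render in a reserved neutral gray.
  The partition coarsens monotonically in k (tested).
- **Operons.** Adjacent genes (sorted by start, one replicon) link when
  `start(next) − end(prev) ≤ operon_gap_max` (default 200 bp, inclusive;
  the gap is the count of bases strictly between the genes, so overlap
  means a negative gap and always links) and, by default, when both genes
  share a strand. Operons are maximal linked runs of ≥ 2 genes. The strand
  requirement reflects how operons are transcribed; it is exposed as a flag
  (`require_same_strand=False` / `--no-same-strand`) so the literal
  distance-only rule remains available. When operon detection runs on the
  union of neighborhood genes (a subset of the replicon), a pair may link
  only if it is also consecutive in the full annotation — disjoint
  neighborhoods are never bridged by an artificial adjacency.

Clustering scope is the union of genes across all neighborhoods of a run,
so recurring gene-context patterns line up across tree leaves. Cluster ids
are assigned 1, 2, … in first-occurrence order (leaves top-to-bottom, genes
left-to-right) and are therefore stable across reruns but may renumber if
the query set changes; membership is input-order invariant.

## Rendering and export

The SVG layer is static and fully deterministic: a rectangular phylogram
(x = cumulative branch length, unit lengths where absent), one `<g>` row
per leaf, and per-row tracks — feature boxes on a residue ruler, or gene
arrows on a shared bp scale so gap sizes are visually comparable across
rows. Fill color encodes cluster, border color encodes operon, a 3 px
border marks query genes, and every glyph carries a `<title>` tooltip. The
palette is a fixed 20-color cycle assigned in first-occurrence order;
after exhaustion colors repeat with a hatch overlay. Appending new leaves
at the bottom of a figure never changes existing color ranks.

JSON documents are validated against pydantic models
(`phylotracks-domains-v1`, `phylotracks-neighborhoods-v1`); the equivalent
JSON Schema files are shipped under `src/phylotracks/schemas/` and are
asserted in the tests to match the models exactly. The `parameters` block
records every applied value including defaults, which is where the default
200 bp threshold is observable downstream.

## Synthetic data generator

`fixtures.synth_genome` lays out genes block by block: planted operons
(same strand within a block, consecutive gaps equal to the block's
`intra_gap`, default 50 bp) and singleton genes, all blocks separated by
`inter_gap` (default 500 bp) with alternating strands. Any linking
threshold strictly between the two gap levels therefore recovers the
planted operons exactly — the package's 200 bp default lies in that
window by construction of the study conditions, not by tuning to a test.
Each gene's protein gets domain hits for one randomly drawn family
(distinct accession sets per family, E-values 1e−40…1e−10, far below the
filter), so family membership is the ground-truth clustering at k = 0.
Proteins are random sequences; hits travel through the TSV channel, which
deliberately decouples feature tests from any search tool.

`fixtures.synth_tree_and_sequences` grows a random topology by sequential
leaf attachment (each new leaf splits a uniformly chosen edge; branch
lengths uniform 0.1–1.0), emits the additive path-length matrix, and
evolves sequences from a random root: per-site substitution counts are
Poisson with mean rate × branch length, replacements uniform over the 20
residues (default rate 0.05 per site per unit length, giving realistic
moderate divergence; rate 0 yields identical sequences). A single integer
seed drives one `numpy` generator per call; there is no global random
state.

What the generator does *not* emulate: indels, codon structure, gene
overlap beyond what the gap parameters produce, horizontal transfer,
pseudogenes, or any correlation between sequence content and domain hits.
Passing tests therefore demonstrate the correctness of the algorithms under
their stated models, not the biological accuracy of k-mer distances or
distance-based operon calling on real genomes.

## Problem sizes and numerical choices

Default validation runs use genomes of 12 genes with two planted operons
(3 + 2 genes), 50 seeds per recovery experiment, and trees of 4–12 leaves,
100 matrices per NJ experiment — small enough to enumerate oracles
exhaustively, large enough to exercise every code path; the full suite and
the acceptance script each finish in seconds. Branch lengths serialize via
`round(x, precision)` with `%g` formatting (default 6 digits), which is the
round-trip precision the tests assert. Distance matrices must be symmetric
within 1e−8 and finite; asymmetry is an error rather than silently
averaged.

## Known limitations

- The builtin k-mer tree is a coarse guide tree; biological conclusions
  about branching order should come from an external aligner + ML tree via
  the adapter interface.
- Redundancy reduction is quadratic in sequence count.
- Operon calling ignores promoters, terminators and expression evidence by
  design; it is a distance heuristic.
- GenBank input is out of scope; annotations enter as GFF3 (CDS features
  with `ID`, optional `locus_tag`/`protein_id`/`product`).
- Identifier lists are newline-separated only, and resolve through a local
  sequence store rather than a remote database.
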