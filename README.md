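# phylotracks

Phylogeny-anchored analysis of protein function signals in prokaryotes:
**domain architectures** and **gene neighborhoods**, organised along a
protein tree so that evolutionary context and genomic context can be read
together. It is aimed at microbiologists and comparative genomicists who
study signal-transduction systems, operon rearrangements and domain
shuffling, and at tool builders who need deterministic, scriptable versions
of the usual "tree + tracks" figure.

## What it computes

Two pipelines share one object model:

- **Domains pipeline** — takes protein sequences (or a ready MSA, or a
  prebuilt Newick tree in *partial mode*), filters raw domain hits (HMMER
  `domtblout` or a generic TSV) by the per-domain independent E-value
  (default ≤ 0.01), resolves overlapping hits greedily by bit score into a
  non-overlapping architecture per protein (tolerating ≤ 20 % overlap of
  the shorter feature), optionally collapses redundant sequences by global
  alignment identity, builds a tree, and sorts the MSA rows into the tree's
  leaf order (optionally enumerating both). A *two-area mode* builds the
  tree from sequence fragments while computing architectures on the
  full-length sequences.
- **Neighborhoods pipeline** — auto-detects its input (sequences, MSA,
  Newick tree or identifier list), resolves each query protein to a gene in
  a GFF3 annotation, extracts up to *w* genes per side (default 5,
  truncating at linear replicon ends, wrapping circular ones), clusters the
  collected genes by **shared domain content** — two genes join a cluster
  when their domain sets differ by at most *k* non-shared domains (symmetric
  difference, default *k* = 0, i.e. identical sets; clusters are connected
  components of that relation) — and calls **operons** as maximal runs of
  same-strand adjacent genes whose intergenic gap is at most **200 bp**
  (inclusive; overlapping genes always link; the threshold and the strand
  rule are configurable).

Tree building is pluggable: the builtin backend is alignment-free (k-mer
set distances, `d = 1 − |K_i ∩ K_j| / min(|K_i|,|K_j|)`) followed by
neighbor joining with the Saitou–Nei criterion
`Q(i,j) = (n−2)·d(i,j) − R_i − R_j`, deterministic tie-breaking and
negative-branch clamping; external aligners/tree builders (e.g. `mafft`,
`fasttree`) attach through a one-line command template. NJ is exact on
additive matrices, which the test suite exploits.

Both pipelines export a schema-validated JSON document (every applied
parameter recorded, including defaults) and a deterministic SVG: gene fill
color = cluster, border color = operon, thick border = query gene; domain
boxes carry `<title>` tooltips.

## Worked example

`examples/02_gene_neighborhoods.py` generates a genome with two planted
operons (intra-operon gaps 50 bp, blocks 500 bp apart) and runs the
pipeline with defaults:

```
queries: 3  (window = 5 genes per side)
  g0001: neighborhood of 6 genes
  g0007: neighborhood of 11 genes
  g0009: neighborhood of 9 genes

clusters (k = 0):
  cluster 1: ['g0001', 'g0012'] domains=['PF00512', 'PF00989', 'PF02518']
  cluster 2: ['g0002', 'g0003', 'g0007', 'g0008'] domains=['PF00072']
  cluster 3: ['g0004', 'g0006'] domains=['PF00015']
  cluster 4: ['g0005', 'g0009', 'g0010', 'g0011'] domains=['PF00512', 'PF02518']

operons (gap <= 200 bp, same strand):
  operon 1: ['g0001', 'g0002', 'g0003']
  operon 2: ['g0004', 'g0005']
planted truth: [['g0001', 'g0002', 'g0003'], ['g0004', 'g0005']]
```

Clusters are groups of genes encoding identical domain sets; the two
detected operons are exactly the planted ones, because every intra-operon
gap (50 bp) is under the 200 bp threshold and every other gap (500 bp) is
over it. The other examples cover architecture resolution, NJ tree
recovery and SVG/JSON generation.

The same runs are available from the shell:

```
phylotracks fixtures --seed 5 --out-dir fx
phylotracks neighborhoods --input ids.txt --annotation fx/genome.gff3 \
    --hits fx/hits.tsv --sequences fx/proteins.fasta --out-prefix out/nb
phylotracks domains --input fx/proteins.fasta --hits fx/hits.tsv --out-prefix out/dom
phylotracks render --model out/nb.neighborhoods.json --ladderize --out out/nb.svg
```

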