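"""Synthetic-data generator with known ground truth.

Emits the complete input set of both pipelines — genome annotation (GFF3),
protein sequences (FASTA), domain hits (TSV), trees (Newick) — from a
single seeded specification, together with a truth record describing the
planted structure (operon runs, domain-family clusters, query genes, the
generating tree and its additive distance matrix). Planted operons use an
intra-operon gap strictly smaller than the inter-block gap, so any linking
threshold between the two recovers them exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skbio import TreeNode

from .io import write_fasta, write_hits_tsv
from .model import (
    FeatureHit,
    FeatureKind,
    FeatureSource,
    Gene,
    GenomeAnnotation,
    PhyloTree,
    Replicon,
    SequenceRecord,
    Strand,
)

__all__ = ["FixtureSpec", "synth_genome", "synth_tree_and_sequences", "GenomeFixture"]

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Domain accession pools used for planted families.
_FAMILY_POOL = [
    ["PF00015"],                       # MCPsignal-like
    ["PF00512", "PF02518"],            # HisKA + HATPase
    ["PF00072"],                       # response regulator
    ["PF00989", "PF00512", "PF02518"], # PAS + kinase core
    ["PF01584"],                       # CheW-like
    ["PF00126", "PF03466"],            # LysR-type
    ["PF00753"],                       # metallo-hydrolase
    ["PF00196"],                       # GerE
]


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset; the seed is mandatory.

    ``planted_operons`` lists (size, intra_gap_bp) runs per replicon;
    blocks (operons and singleton genes) are separated by ``inter_gap`` bp.
    Genes are assigned to domain families so that family membership is the
    ground-truth clustering at k=0.
    """

    seed: int
    n_replicons: int = 1
    genes_per_replicon: int = 12
    planted_operons: list[tuple[int, int]] = field(
        default_factory=lambda: [(3, 50), (2, 50)]
    )
    inter_gap: int = 500
    domain_families: list[list[str]] = field(
        default_factory=lambda: [list(f) for f in _FAMILY_POOL[:4]]
    )
    n_queries: int = 3
    tree_leaves: int = 6
    substitution_rate: float = 0.05
    gene_length_range: tuple[int, int] = (300, 1500)
    domainless_fraction: float = 0.0
    circular: bool = False

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for size, intra in self.planted_operons:
            if size < 2:
                raise ValueError("planted operons need >= 2 genes")
            if intra >= self.inter_gap:
                raise ValueError(
                    f"intra_gap {intra} must be < inter_gap {self.inter_gap}"
                )
        if sum(s for s, _ in self.planted_operons) > self.genes_per_replicon:
            raise ValueError("planted operons exceed genes_per_replicon")


@dataclass
class GenomeFixture:
    """One generated dataset plus its ground truth."""

    annotation: GenomeAnnotation
    gff3: str
    fasta: str
    hits_tsv: str
    truth: dict


def synth_genome(spec: FixtureSpec) -> GenomeFixture:
    """Generate a genome annotation with planted operons and domain families.

    Within a planted operon all genes share a strand and consecutive gaps
    equal the operon's intra_gap; blocks are separated by inter_gap and
    alternate strands so no accidental run forms. Each gene's protein
    receives hits for its family's accessions with E-values far below the
    default cutoff. Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    genes: list[Gene] = []
    records: list[SequenceRecord] = []
    hits: list[FeatureHit] = []
    truth_operons: list[list[str]] = []
    truth_families: dict[str, list[str]] = {}
    replicons: dict[str, Replicon] = {}

    fam_sets = [frozenset(f) for f in spec.domain_families]
    gene_no = 0
    for r in range(spec.n_replicons):
        rid = f"rep{r + 1}"
        rep_genes: list[Gene] = []
        # block layout: planted operons first, then singletons
        blocks: list[tuple[int, Optional[int]]] = [
            (size, intra) for size, intra in spec.planted_operons
        ]
        n_single = spec.genes_per_replicon - sum(s for s, _ in spec.planted_operons)
        blocks += [(1, None)] * n_single
        pos = int(rng.integers(100, 300))
        for b_idx, (size, intra) in enumerate(blocks):
            strand = Strand.FORWARD if b_idx % 2 == 0 else Strand.REVERSE
            members: list[str] = []
            for g_in_block in range(size):
                gene_no += 1
                gid = f"g{gene_no:04d}"
                pid = f"WP_{900000000 + gene_no}.1"
                length = int(
                    rng.integers(spec.gene_length_range[0], spec.gene_length_range[1])
                )
                length -= length % 3
                gene = Gene(
                    gene_id=gid,
                    replicon_id=rid,
                    start=pos,
                    end=pos + length,
                    strand=strand,
                    locus_tag=f"LT_{gene_no:04d}",
                    protein_id=pid,
                    product=f"synthetic protein {gene_no}",
                )
                rep_genes.append(gene)
                members.append(gid)
                # protein + domain hits
                n_res = max(length // 3, 210)  # room for 3-domain families
                seq = "".join(rng.choice(list(_AA20), size=n_res))
                records.append(
                    SequenceRecord(id=pid, residues=seq, description=f"{gid} {rid}")
                )
                if rng.random() >= spec.domainless_fraction:
                    fam_idx = int(rng.integers(0, len(fam_sets)))
                    fam_key = ",".join(sorted(fam_sets[fam_idx]))
                    truth_families.setdefault(fam_key, []).append(gid)
                    offset = 1
                    for acc in spec.domain_families[fam_idx]:
                        dom_len = min(60, n_res - offset)
                        hits.append(
                            FeatureHit(
                                protein_id=pid,
                                kind=FeatureKind.DOMAIN,
                                source=FeatureSource.PFAM,
                                accession=acc,
                                name=acc.replace("PF", "Dom"),
                                start=offset,
                                end=offset + dom_len - 1,
                                bit_score=float(rng.uniform(50, 200)),
                                evalue=float(10.0 ** rng.uniform(-40, -10)),
                            )
                        )
                        offset += dom_len + 5
                pos = gene.end + (intra if g_in_block < size - 1 else spec.inter_gap)
            if size >= 2:
                truth_operons.append(members)
        rep_len = (rep_genes[-1].end + spec.inter_gap) if rep_genes else 1000
        replicons[rid] = Replicon(
            replicon_id=rid,
            length=rep_len,
            circular=spec.circular,
            genes=rep_genes,
        )
        genes.extend(rep_genes)

    annotation = GenomeAnnotation(replicons=replicons)
    query_genes = [
        genes[i]
        for i in sorted(
            rng.choice(len(genes), size=min(spec.n_queries, len(genes)), replace=False)
        )
    ]
    truth = {
        "operons": truth_operons,
        "families": {k: sorted(v) for k, v in sorted(truth_families.items())},
        "queries": [g.gene_id for g in query_genes],
        "query_proteins": [g.protein_id for g in query_genes],
        "intra_gaps": sorted({i for _, i in spec.planted_operons}),
        "inter_gap": spec.inter_gap,
        "seed": spec.seed,
    }
    return GenomeFixture(
        annotation=annotation,
        gff3=_to_gff3(annotation),
        fasta=write_fasta(records),
        hits_tsv=write_hits_tsv(hits),
        truth=truth,
    )


def _to_gff3(annotation: GenomeAnnotation) -> str:
    lines = ["##gff-version 3"]
    for rid in sorted(annotation.replicons):
        rep = annotation.replicons[rid]
        lines.append(f"##sequence-region {rid} 1 {rep.length}")
        if rep.circular:
            lines.append(
                f"{rid}\tsynth\tregion\t1\t{rep.length}\t.\t+\t.\t"
                f"ID=region-{rid};Is_circular=true"
            )
        for g in rep.genes:
            attrs = [f"ID={g.gene_id}"]
            if g.locus_tag:
                attrs.append(f"locus_tag={g.locus_tag}")
            if g.protein_id:
                attrs.append(f"protein_id={g.protein_id}")
            if g.product:
                attrs.append(f"product={g.product}")
            lines.append(
                f"{rid}\tsynth\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand.value}\t0\t{';'.join(attrs)}"
            )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Tree + sequence evolution


def synth_tree_and_sequences(
    spec: FixtureSpec, seq_length: int = 120
) -> tuple[PhyloTree, list[SequenceRecord], np.ndarray]:
    """Random tree by sequential leaf attachment, sequences evolved along it.

    Returns the tree, the leaf sequences, and the tree's additive pairwise
    distance matrix (path lengths, leaf order = depth-first tip order).
    Per-site substitution counts along a branch are Poisson with mean
    ``substitution_rate * branch_length``; replacements are uniform over the
    20 standard residues, so rate 0 leaves all sequences identical.
    """
    if spec.tree_leaves < 3:
        raise ValueError("need at least 3 leaves")
    rng = np.random.default_rng(spec.seed)
    names = [f"T{i + 1:03d}" for i in range(spec.tree_leaves)]

    def bl() -> float:
        return float(rng.uniform(0.1, 1.0))

    a, b = TreeNode(name=names[0]), TreeNode(name=names[1])
    a.length, b.length = bl(), bl()
    root = TreeNode(children=[a, b])
    edges = [a, b]  # nodes whose parent-edge can be split
    for name in names[2:]:
        target = edges[int(rng.integers(0, len(edges)))]
        parent = target.parent
        mid = TreeNode()
        old_len = target.length
        split = float(rng.uniform(0.2, 0.8))
        idx = parent.children.index(target)
        parent.children[idx] = mid
        mid.parent = parent
        mid.length = old_len * split
        target.parent = mid
        target.length = old_len * (1 - split)
        leaf = TreeNode(name=name)
        leaf.length = bl()
        mid.children = [target, leaf]
        leaf.parent = mid
        edges.extend([mid, leaf])

    # additive distances by path length, tips in depth-first order
    tips = list(root.tips())
    n = len(tips)
    dmat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dmat[i, j] = dmat[j, i] = _path_length(tips[i], tips[j])

    # evolve sequences from a random root sequence
    root_seq = rng.integers(0, 20, size=seq_length)

    seqs: dict[str, np.ndarray] = {}

    def evolve(node: TreeNode, seq: np.ndarray) -> None:
        if node.length:
            lam = spec.substitution_rate * node.length
            nsub = rng.poisson(lam, size=seq_length)
            seq = seq.copy()
            for site in np.nonzero(nsub)[0]:
                seq[site] = rng.integers(0, 20)
        if node.is_tip():
            seqs[node.name] = seq
        else:
            for c in node.children:
                evolve(c, seq)

    for c in root.children:
        evolve(c, root_seq)

    records = [
        SequenceRecord(
            id=t.name, residues="".join(_AA20[k] for k in seqs[t.name])
        )
        for t in tips
    ]
    return root, records, dmat


def _path_length(a: TreeNode, b: TreeNode) -> float:
    anc_a = {}
    node, acc = a, 0.0
    while node is not None:
        anc_a[id(node)] = acc
        acc += node.length or 0.0
        node = node.parent
    node, acc = b, 0.0
    while id(node) not in anc_a:
        acc += node.length or 0.0
        node = node.parent
    return acc + anc_a[id(node)]


def write_fixture(fixture: GenomeFixture, out_dir) -> dict[str, str]:
    """Write a genome fixture's files (GFF3, FASTA, TSV, truth.json)."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": out / "genome.gff3",
        "fasta": out / "proteins.fasta",
        "hits": out / "hits.tsv",
        "truth": out / "truth.json",
    }
    paths["gff3"].write_text(fixture.gff3)
    paths["fasta"].write_text(fixture.fasta)
    paths["hits"].write_text(fixture.hits_tsv)
    paths["truth"].write_text(json.dumps(fixture.truth, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in paths.items()}
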