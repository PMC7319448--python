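"""Gene-neighborhood pipeline: neighborhood extraction around query genes,
domain-content clustering of the neighboring genes, and operon detection by
intergenic distance.

The intergenic gap between two adjacent genes is ``start(next) - end(prev)``
in half-open coordinates, i.e. the number of bases strictly between them;
overlapping genes have a negative gap and are always linked. The default
linking threshold is 200 bp, inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from . import io as ptio
from .domains import build_architectures, kmer_distance_matrix, nj_tree
from .model import (
    DomainArchitecture,
    DomainsConfig,
    Gene,
    GeneCluster,
    GenomeAnnotation,
    Neighborhood,
    NeighborhoodsConfig,
    Operon,
    PhyloTree,
    SequenceRecord,
    Strand,
)

__all__ = [
    "extract_neighborhood",
    "gene_domain_set",
    "compatible",
    "cluster_genes",
    "detect_operons",
    "run_neighborhoods_pipeline",
    "NeighborhoodsResult",
]


def extract_neighborhood(
    annotation: GenomeAnnotation, query_gene_id: str, window: int
) -> Neighborhood:
    """Collect up to ``window`` genes on each side of the query gene.

    On linear replicons the window truncates at the replicon ends (the
    ``truncated_*`` flags record this); on circular replicons it wraps
    around the origin and the ``wrapped`` flag is set, genes being reported
    in wrapped order with their original (unwrapped) coordinates.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    hits = [
        (rid, idx)
        for rid, rep in annotation.replicons.items()
        for idx, g in enumerate(rep.genes)
        if g.gene_id == query_gene_id
    ]
    if not hits:
        raise KeyError(f"unknown query gene {query_gene_id!r}")
    if len(hits) > 1:
        raise KeyError(f"query gene id {query_gene_id!r} is ambiguous")
    rid, qi = hits[0]
    rep = annotation.replicons[rid]
    genes = rep.genes
    n = len(genes)
    if rep.circular and n > 2 * window:
        if rep.length is None:
            raise ValueError(
                f"replicon {rid} is circular but has no length; cannot wrap"
            )
        idxs = [(qi + off) % n for off in range(-window, window + 1)]
        wrapped = any(idxs[k] > idxs[k + 1] for k in range(len(idxs) - 1))
        return Neighborhood(
            query_gene_id=query_gene_id,
            genes=[genes[i] for i in idxs],
            wrapped=wrapped,
        )
    lo, hi = max(0, qi - window), min(n, qi + window + 1)
    return Neighborhood(
        query_gene_id=query_gene_id,
        genes=genes[lo:hi],
        truncated_left=qi - window < 0,
        truncated_right=qi + window + 1 > n,
    )


def gene_domain_set(
    gene: Gene, architectures: dict[str, DomainArchitecture]
) -> frozenset[str]:
    """The set of domain accessions encoded by a gene's protein.

    Duplicate domains collapse (set, not multiset); transmembrane and
    low-complexity features are excluded; a gene with no architecture has
    the empty set.
    """
    if gene.protein_id and gene.protein_id in architectures:
        return architectures[gene.protein_id].domain_accessions
    return frozenset()


def compatible(set_a: frozenset[str], set_b: frozenset[str], k: int) -> bool:
    """True iff the two domain sets differ by at most ``k`` non-shared
    domains (symmetric-difference cardinality).

    Two empty sets are never compatible: domain-less genes share no domain,
    so they are never clustered.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if not set_a and not set_b:
        return False
    return len(set_a ^ set_b) <= k


def cluster_genes(
    genes: Sequence[Gene],
    architectures: dict[str, DomainArchitecture],
    k: int = 0,
) -> list[GeneCluster]:
    """Cluster genes by shared domain content.

    Clusters are the connected components of the pairwise compatibility
    graph (single linkage); at k=0 this reduces to grouping by identical
    non-empty domain set. Domain-less genes stay unclustered. Cluster ids
    are contiguous from 1 in order of first member occurrence in ``genes``.
    """
    genes = list(genes)
    sets = [gene_domain_set(g, architectures) for g in genes]
    n = len(genes)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[max(rx, ry)] = min(rx, ry)

    if k == 0:
        by_set: dict[frozenset[str], int] = {}
        for i, s in enumerate(sets):
            if not s:
                continue
            if s in by_set:
                union(by_set[s], i)
            else:
                by_set[s] = i
    else:
        for i in range(n):
            if not sets[i]:
                continue
            for j in range(i + 1, n):
                if sets[j] and compatible(sets[i], sets[j], k):
                    union(i, j)

    components: dict[int, list[int]] = {}
    for i in range(n):
        if not sets[i]:
            continue
        components.setdefault(find(i), []).append(i)

    clusters: list[GeneCluster] = []
    for root in sorted(components, key=lambda r: min(components[r])):
        members = sorted(components[root])
        clusters.append(
            GeneCluster(
                cluster_id=len(clusters) + 1,
                member_gene_ids=[genes[i].gene_id for i in members],
                domain_signature=sets[members[0]],
            )
        )
    return clusters


def detect_operons(
    genes: Sequence[Gene],
    config: NeighborhoodsConfig,
    adjacency: Optional[set[tuple[str, str]]] = None,
) -> list[Operon]:
    """Find maximal runs of adjacent genes linked by small intergenic gaps.

    Adjacent genes a, b (sorted by start on one replicon) are linked iff
    ``start(b) - end(a) <= operon_gap_max`` (inclusive; negative gaps, i.e.
    overlaps, always link) and, when ``require_same_strand``, both lie on
    the same strand. Operons are maximal linked runs of >= 2 genes.

    ``adjacency`` optionally restricts linking to pairs known to be
    genomically consecutive, for gene lists that are a subset of a replicon.
    """
    genes = list(genes)
    for a, b in zip(genes, genes[1:]):
        if a.replicon_id != b.replicon_id:
            raise ValueError("detect_operons expects genes of one replicon")
        if (b.start, b.end) < (a.start, a.end):
            raise ValueError("genes must be sorted by start")
    operons: list[Operon] = []
    run = [0] if genes else []
    for i in range(1, len(genes)):
        a, b = genes[i - 1], genes[i]
        gap = b.start - a.end
        linked = gap <= config.operon_gap_max
        if linked and config.require_same_strand and a.strand != b.strand:
            linked = False
        if linked and adjacency is not None:
            linked = (a.gene_id, b.gene_id) in adjacency
        if linked:
            run.append(i)
        else:
            if len(run) >= 2:
                operons.append(_make_operon(genes, run, len(operons) + 1, config))
            run = [i]
    if len(run) >= 2:
        operons.append(_make_operon(genes, run, len(operons) + 1, config))
    return operons


def _make_operon(
    genes: list[Gene], idxs: list[int], operon_id: int, config: NeighborhoodsConfig
) -> Operon:
    members = [genes[i] for i in idxs]
    strand = members[0].strand if config.require_same_strand else None
    return Operon(
        operon_id=operon_id,
        replicon_id=members[0].replicon_id,
        strand=strand,
        member_gene_ids=[g.gene_id for g in members],
    )


@dataclass
class NeighborhoodsResult:
    tree: Optional[PhyloTree]
    neighborhoods: list[Neighborhood]
    clusters: list[GeneCluster]
    operons: list[Operon]
    architectures: dict[str, DomainArchitecture] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)


def run_neighborhoods_pipeline(
    input_text: str,
    annotation: GenomeAnnotation,
    hits: Sequence,
    config: NeighborhoodsConfig,
    sequence_store: Optional[dict[str, SequenceRecord]] = None,
    domains_config: Optional[DomainsConfig] = None,
) -> NeighborhoodsResult:
    """Run the gene-neighborhood pipeline end to end.

    The input may be protein sequences, an MSA, a Newick tree or a list of
    protein identifiers; its type is detected automatically. Sequences/MSA/
    id-list inputs get a tree built with the builtin backend (ids are
    resolved through ``sequence_store``, the local stand-in for a remote
    sequence database); a Newick input is used verbatim. Query proteins are
    resolved to genes through the annotation; one neighborhood is extracted
    per query, clustering runs over the union of all neighborhood genes,
    and operons are detected per replicon restricted to the neighborhood
    spans (pairs must also be consecutive in the full annotation).
    """
    domains_config = domains_config or DomainsConfig()
    input_type = ptio.detect_input_type(input_text)

    tree: Optional[PhyloTree] = None
    tree_source = "builtin_nj"
    if input_type == "newick":
        tree = ptio.read_newick(input_text)
        query_ids = [ptio.parse_leaf_id(t.name) for t in tree.tips()]
        tree_source = "user"
    elif input_type in ("sequences", "alignment"):
        records = ptio.read_fasta(input_text)
        query_ids = [ptio.parse_leaf_id(r.id) for r in records]
        if len(records) >= 3:
            tree = nj_tree(
                kmer_distance_matrix(records, k=domains_config.kmer_size)
            )
    else:  # id_list
        ids = [ln.strip() for ln in input_text.splitlines() if ln.strip()]
        query_ids = [ptio.parse_leaf_id(i) for i in ids]
        if sequence_store is None:
            raise ValueError("id_list input requires a sequence store")
        missing = [i for i in query_ids if i not in sequence_store]
        if missing:
            raise KeyError(f"ids not in sequence store: {missing}")
        records = [sequence_store[i] for i in query_ids]
        if len(records) >= 3:
            tree = nj_tree(
                kmer_distance_matrix(records, k=domains_config.kmer_size)
            )

    # resolve query proteins to genes
    missing_ids: list[str] = []
    query_genes: list[Gene] = []
    for pid in query_ids:
        try:
            query_genes.append(annotation.find_gene(pid))
        except KeyError:
            missing_ids.append(pid)
    if missing_ids:
        raise KeyError(f"query proteins without genes in annotation: {missing_ids}")

    architectures = build_architectures(hits, domains_config) if hits else {}

    # order neighborhoods by tree leaf order when a tree exists
    if tree is not None:
        order = {pid: i for i, pid in enumerate(
            ptio.parse_leaf_id(t.name) for t in tree.tips()
        )}
        query_genes.sort(key=lambda g: order.get(g.protein_id or g.gene_id, 1 << 30))

    neighborhoods = [
        extract_neighborhood(annotation, g.gene_id, config.window)
        for g in query_genes
    ]

    # clustering over the union of all neighborhood genes, in display order
    seen: set[str] = set()
    union_genes: list[Gene] = []
    for nb in neighborhoods:
        for g in nb.genes:
            if g.gene_id not in seen:
                seen.add(g.gene_id)
                union_genes.append(g)
    clusters = cluster_genes(union_genes, architectures, k=config.nonshared_max)

    # attach domain sets to genes for rendering/export
    for g in union_genes:
        g.domain_accessions = gene_domain_set(g, architectures)

    # operons per replicon, restricted to neighborhood spans; linking
    # requires genomic adjacency in the full annotation
    operons: list[Operon] = []
    by_replicon: dict[str, list[Gene]] = {}
    for g in union_genes:
        by_replicon.setdefault(g.replicon_id, []).append(g)
    for rid in sorted(by_replicon):
        rep_genes = sorted(by_replicon[rid], key=lambda g: (g.start, g.end))
        full = annotation.replicons[rid].genes
        adjacency = {
            (a.gene_id, b.gene_id) for a, b in zip(full, full[1:])
        }
        for op in detect_operons(rep_genes, config, adjacency=adjacency):
            operons.append(
                Operon(
                    operon_id=len(operons) + 1,
                    replicon_id=op.replicon_id,
                    strand=op.strand,
                    member_gene_ids=op.member_gene_ids,
                )
            )

    metadata = {
        "pipeline": "neighborhoods",
        "input_type": input_type,
        "tree_source": tree_source,
        "window": config.window,
        "nonshared_max": config.nonshared_max,
        "operon_gap_max": config.operon_gap_max,
        "require_same_strand": config.require_same_strand,
        "evalue_max": domains_config.evalue_max,
        "n_queries": len(query_genes),
        "warnings": [],
    }
    if any(nb.wrapped for nb in neighborhoods):
        metadata["warnings"].append(
            "one or more neighborhoods wrap a circular replicon origin"
        )
    return NeighborhoodsResult(
        tree=tree,
        neighborhoods=neighborhoods,
        clusters=clusters,
        operons=operons,
        architectures=architectures,
        metadata=metadata,
    )
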