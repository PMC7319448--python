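"""Domain-architecture pipeline: hit filtering, overlap resolution,
redundancy reduction, built-in distance/NJ tree construction, MSA ordering.

The built-in tree backend (k-mer distance + neighbor joining) is a
dependency-free fallback and is always labelled ``builtin_nj`` in result
metadata so its trees are never mistaken for alignment-based ML/FastTree
output produced through an external adapter.
"""

from __future__ import annotations

import re
import shlex
import subprocess
import tempfile
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from skbio import TreeNode

from . import io as ptio
from .model import (
    GAP,
    Alignment,
    DistanceMatrix,
    DomainArchitecture,
    DomainsConfig,
    FeatureHit,
    FeatureKind,
    PhyloTree,
    SequenceRecord,
)

__all__ = [
    "filter_hits",
    "resolve_overlaps",
    "build_architectures",
    "reduce_redundancy",
    "kmer_distance_matrix",
    "nj_tree",
    "sort_alignment_by_tree",
    "enumerate_leaves",
    "run_domains_pipeline",
    "DomainsResult",
]


# ---------------------------------------------------------------------------
# Feature filtering and overlap resolution


def filter_hits(hits: Sequence[FeatureHit], config: DomainsConfig) -> list[FeatureHit]:
    """Drop domain hits whose independent E-value exceeds the cutoff.

    Transmembrane and low-complexity features carry no meaningful E-value
    and bypass the filter.
    """
    kept = []
    for h in hits:
        if h.kind is not FeatureKind.DOMAIN:
            kept.append(h)
        elif h.evalue is not None and h.evalue <= config.evalue_max:
            kept.append(h)
    return kept


def resolve_overlaps(
    hits: Sequence[FeatureHit], config: DomainsConfig
) -> DomainArchitecture:
    """Resolve conflicting domain hits into one non-overlapping architecture.

    Greedy by descending bit score (ties: smaller E-value, then smaller
    start): a hit is accepted iff its overlap with every already-accepted
    domain hit is at most ``overlap_fraction_max`` of the shorter of the
    pair. Non-domain features never conflict.
    """
    hits = list(hits)
    if not hits:
        raise ValueError("no hits to resolve")
    protein_ids = {h.protein_id for h in hits}
    if len(protein_ids) != 1:
        raise ValueError(f"hits span multiple proteins: {sorted(protein_ids)}")
    domain_hits = [h for h in hits if h.kind is FeatureKind.DOMAIN]
    other_hits = [h for h in hits if h.kind is not FeatureKind.DOMAIN]

    def priority(h: FeatureHit):
        ev = h.evalue if h.evalue is not None else 0.0
        return (-h.bit_score, ev, h.start, h.end, h.accession)

    accepted: list[FeatureHit] = []
    for h in sorted(domain_hits, key=priority):
        ok = True
        for a in accepted:
            limit = config.overlap_fraction_max * min(len(h), len(a))
            if h.overlap(a) > limit:
                ok = False
                break
        if ok:
            accepted.append(h)
    return DomainArchitecture(
        protein_id=hits[0].protein_id, features=accepted + other_hits
    )


def build_architectures(
    hits: Sequence[FeatureHit], config: DomainsConfig
) -> dict[str, DomainArchitecture]:
    """Filter and resolve hits for every protein present in ``hits``."""
    by_protein: dict[str, list[FeatureHit]] = defaultdict(list)
    for h in filter_hits(hits, config):
        by_protein[h.protein_id].append(h)
    return {
        pid: resolve_overlaps(phits, config)
        for pid, phits in sorted(by_protein.items())
    }


# ---------------------------------------------------------------------------
# Redundancy reduction (greedy longest-first, exact DP identity)

_aligner = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=-1,
    extend_gap_score=-1,
)


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment length, with match=1,
    mismatch=0 and a linear gap penalty of -1."""
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    return counts.identities / aln.length


def reduce_redundancy(
    records: Sequence[SequenceRecord], identity_threshold: float
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Greedy incremental clustering of ungapped sequences, longest first.

    Each record joins the first representative whose pairwise identity is
    at least the threshold, else becomes a new representative. Returns the
    representatives (in selection order) and a membership map id ->
    representative id covering every input.
    """
    if not records:
        raise ValueError("no records")
    if not (0.0 < identity_threshold <= 1.0):
        raise ValueError("identity threshold must be in (0, 1]")
    gapped = [r.id for r in records if GAP in r.residues]
    if gapped:
        raise ValueError(
            f"gapped records {gapped}: reduce before aligning"
        )
    order = sorted(records, key=lambda r: (-len(r.residues), r.id))
    reps: list[SequenceRecord] = []
    membership: dict[str, str] = {}
    for rec in order:
        home = None
        for rep in reps:
            if pairwise_identity(rec.residues, rep.residues) >= identity_threshold:
                home = rep
                break
        if home is None:
            reps.append(rec)
            membership[rec.id] = rec.id
        else:
            membership[rec.id] = home.id
    return reps, membership


# ---------------------------------------------------------------------------
# Built-in tree backend: k-mer distances + neighbor joining


def kmer_distance_matrix(
    records: Sequence[SequenceRecord], k: int = 3
) -> DistanceMatrix:
    """Alignment-free distances: d(i,j) = 1 - |Ki ∩ Kj| / min(|Ki|, |Kj|)
    over the sets of length-k substrings of the ungapped sequences."""
    if len(records) < 3:
        raise ValueError("need at least 3 records for a distance matrix")
    if k < 1:
        raise ValueError("k must be >= 1")
    kmer_sets = []
    for r in records:
        seq = r.ungapped
        if len(seq) < k:
            raise ValueError(f"sequence {r.id} shorter than k={k}")
        kmer_sets.append({seq[i : i + k] for i in range(len(seq) - k + 1)})
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(kmer_sets[i] & kmer_sets[j])
            denom = min(len(kmer_sets[i]), len(kmer_sets[j]))
            d[i, j] = d[j, i] = 1.0 - shared / denom
    return DistanceMatrix(labels=[r.id for r in records], d=d)


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Neighbor joining (Saitou-Nei) with deterministic tie-breaking.

    At every step the pair minimising Q(i,j) = (n-2) d(i,j) - R(i) - R(j)
    is joined; ties are broken by the lexicographically smallest pair of
    node labels, an internal node being labelled by the smallest leaf it
    contains. Negative branch lengths are clamped to zero and the deficit
    moved onto the sibling branch, preserving the path length between the
    joined pair. The final three nodes are attached to an unrooted
    trifurcating root with closed-form branch lengths.
    """
    labels = list(matrix.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("NJ needs at least 3 taxa")
    d = {i: {j: float(matrix.d[i, j]) for j in range(n) if j != i} for i in range(n)}
    nodes: dict[int, TreeNode] = {
        i: TreeNode(name=labels[i]) for i in range(n)
    }
    tag: dict[int, str] = {i: labels[i] for i in range(n)}  # min-leaf label
    next_id = n
    active = set(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i][j] for j in active if j != i) for i in active}
        best = None
        for i in sorted(active):
            for j in sorted(active):
                if j <= i:
                    continue
                q = (m - 2) * d[i][j] - r[i] - r[j]
                pair_key = tuple(sorted((tag[i], tag[j])))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * d[i][j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i][j] - li
        # clamp negatives, shifting the deficit to the sibling branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = TreeNode()
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = li, lj
        parent.extend([ci, cj])
        new = next_id
        next_id += 1
        nodes[new] = parent
        tag[new] = min(tag[i], tag[j])
        d[new] = {}
        for k_ in active:
            if k_ in (i, j):
                continue
            dk = 0.5 * (d[i][k_] + d[j][k_] - d[i][j])
            d[new][k_] = dk
            d[k_][new] = dk
        active.discard(i)
        active.discard(j)
        active.add(new)

    a, b, c = sorted(active, key=lambda x: tag[x])
    root = TreeNode()
    la = 0.5 * (d[a][b] + d[a][c] - d[b][c])
    lb = 0.5 * (d[a][b] + d[b][c] - d[a][c])
    lc = 0.5 * (d[a][c] + d[b][c] - d[a][b])
    for idx, ln in ((a, la), (b, lb), (c, lc)):
        child = nodes[idx]
        child.length = max(ln, 0.0)
        root.append(child)
    return root


# ---------------------------------------------------------------------------
# MSA ordering and enumeration


def _leaf_order_ids(tree: PhyloTree) -> list[str]:
    return [ptio.parse_leaf_id(tip.name) for tip in tree.tips()]


def sort_alignment_by_tree(alignment: Alignment, tree: PhyloTree) -> Alignment:
    """Permute MSA rows into the tree's depth-first leaf order.

    Leaf names are resolved to record ids with ``parse_leaf_id``; the
    mapping must be a bijection.
    """
    order = _leaf_order_ids(tree)
    by_id = {r.id: r for r in alignment.records}
    missing_records = [i for i in order if i not in by_id]
    missing_leaves = sorted(set(by_id) - set(order))
    if missing_records or missing_leaves:
        parts = []
        if missing_records:
            parts.append(f"leaves without alignment rows: {missing_records}")
        if missing_leaves:
            parts.append(f"alignment rows without leaves: {missing_leaves}")
        raise ValueError("tree/alignment mismatch; " + "; ".join(parts))
    return Alignment(
        records=[by_id[i] for i in order], aligned=alignment.aligned
    )


_ENUM_PREFIX = re.compile(r"^\d+\. ")


def enumerate_leaves(
    tree: PhyloTree, alignment: Alignment
) -> tuple[PhyloTree, Alignment]:
    """Prefix tree leaves and MSA rows with matching '1. ', '2. ', … indices.

    The alignment must already be in tree leaf order; re-enumerating an
    already enumerated pair is an error.
    """
    tips = list(tree.tips())
    if any(_ENUM_PREFIX.match(t.name) for t in tips) or any(
        _ENUM_PREFIX.match(r.id) for r in alignment.records
    ):
        raise ValueError("leaves are already enumerated")
    order = _leaf_order_ids(tree)
    if order != [r.id for r in alignment.records]:
        raise ValueError("alignment must be sorted to tree leaf order first")
    new_tree = tree.copy()
    for idx, tip in enumerate(new_tree.tips(), start=1):
        tip.name = f"{idx}. {tip.name}"
    new_records = [
        SequenceRecord(
            id=f"{idx}. {r.id}", residues=r.residues, description=r.description
        )
        for idx, r in enumerate(alignment.records, start=1)
    ]
    return new_tree, Alignment(records=new_records, aligned=alignment.aligned)


# ---------------------------------------------------------------------------
# External tool adapters


def run_external_tool(template: str, input_text: str) -> str:
    """Run a shell command template with {input}/{output} file placeholders
    and return the output file's text. Used for MSA and tree adapters."""
    with tempfile.TemporaryDirectory() as tmp:
        in_path = Path(tmp) / "input.fasta"
        out_path = Path(tmp) / "output.txt"
        in_path.write_text(input_text)
        cmd = template.format(input=str(in_path), output=str(out_path))
        proc = subprocess.run(
            shlex.split(cmd), capture_output=True, text=True
        )
        if proc.returncode != 0:
            raise RuntimeError(
                f"external tool failed ({proc.returncode}): {proc.stderr[:500]}"
            )
        if out_path.exists():
            return out_path.read_text()
        return proc.stdout


# ---------------------------------------------------------------------------
# Pipeline driver


@dataclass
class DomainsResult:
    tree: Optional[PhyloTree]
    alignment: Optional[Alignment]
    architectures: dict[str, DomainArchitecture]
    metadata: dict = field(default_factory=dict)


def run_domains_pipeline(
    input_text: str,
    config: DomainsConfig,
    hits: Optional[Sequence[FeatureHit]] = None,
    tree_text: Optional[str] = None,
    fragments_text: Optional[str] = None,
    aligner_cmd: Optional[str] = None,
    treebuilder_cmd: Optional[str] = None,
) -> DomainsResult:
    """Run the domain-architecture pipeline end to end.

    Steps in order: optional redundancy reduction, feature filtering and
    overlap resolution (skipped with ``skip_features``), alignment (external
    adapter, or passthrough for pre-aligned input), tree construction
    (builtin k-mer + NJ, external adapter, or a user tree in partial mode),
    MSA sorting to leaf order and optional enumeration.

    Two-area mode: when ``fragments_text`` is given the tree is built from
    the fragment sequences while architectures are computed on the
    full-length input; the two sets are joined by identical ids.

    Metadata records every parameter actually applied, including defaults.
    """
    if config.mode == "partial" and tree_text is None:
        raise ValueError("partial mode requires a tree")
    if config.skip_features and config.mode == "partial":
        raise ValueError(
            "nothing to do: features skipped and no tree to build in partial mode"
        )

    input_type = ptio.detect_input_type(input_text)
    if input_type == "newick":
        raise ValueError(
            "the domains pipeline takes sequences or an alignment as primary "
            "input; pass a tree via tree_text with mode='partial'"
        )
    if input_type == "id_list":
        raise ValueError("identifier lists need a sequence store; provide FASTA")
    records = ptio.read_fasta(input_text)
    prealigned = input_type == "alignment"

    metadata: dict = {
        "pipeline": "domains",
        "input_type": input_type,
        "mode": config.mode,
        "evalue_max": config.evalue_max,
        "overlap_fraction_max": config.overlap_fraction_max,
        "identity_threshold": config.identity_threshold,
        "enumerate_leaves": config.enumerate_leaves,
        "skip_features": config.skip_features,
        "tree_backend": config.tree_backend,
        "aligner_backend": config.aligner_backend,
        "kmer_size": config.kmer_size,
        "two_area": fragments_text is not None,
        "warnings": [],
    }

    # 1. redundancy reduction (unaligned input only)
    membership = None
    if config.identity_threshold is not None:
        if prealigned:
            raise ValueError("reduce before aligning: input is already aligned")
        records, membership = reduce_redundancy(records, config.identity_threshold)
        metadata["redundancy_membership"] = dict(sorted(membership.items()))

    # 2. feature identification is external; filtering + resolution are ours
    architectures: dict[str, DomainArchitecture] = {}
    if not config.skip_features and hits is not None:
        architectures = build_architectures(hits, config)

    # 3-4. alignment and tree
    tree: Optional[PhyloTree]
    alignment: Optional[Alignment]
    tree_source_records = records
    if fragments_text is not None:
        frag_records = ptio.read_fasta(fragments_text)
        frag_ids, full_ids = {r.id for r in frag_records}, {r.id for r in records}
        if frag_ids != full_ids:
            raise ValueError(
                "two-area mode requires identical ids in both areas; "
                f"difference: {sorted(frag_ids ^ full_ids)}"
            )
        tree_source_records = frag_records
        prealigned = False

    if config.mode == "partial":
        tree = ptio.read_newick(tree_text)
        metadata["tree_source"] = "user"
        alignment = (
            Alignment(records=records, aligned=prealigned)
            if len(records) >= 2
            else None
        )
    else:
        if prealigned:
            alignment = Alignment(records=records, aligned=True)
            metadata["alignment_source"] = "user"
        elif aligner_cmd is not None:
            aligned_text = run_external_tool(
                aligner_cmd, ptio.write_fasta(tree_source_records)
            )
            alignment = Alignment(records=ptio.read_fasta(aligned_text), aligned=True)
            metadata["alignment_source"] = "external"
        else:
            alignment = Alignment(
                records=list(tree_source_records), aligned=False
            )
            metadata["alignment_source"] = "builtin_identity_passthrough"

        if config.tree_backend == "external":
            if treebuilder_cmd is None:
                raise ValueError("external tree backend needs a command template")
            newick = run_external_tool(
                treebuilder_cmd, ptio.write_fasta(alignment.records)
            )
            tree = ptio.read_newick(newick)
            metadata["tree_source"] = "external"
        else:
            dm = kmer_distance_matrix(tree_source_records, k=config.kmer_size)
            tree = nj_tree(dm)
            metadata["tree_source"] = "builtin_nj"

    # two-area: tree from fragments, alignment/architectures on full length
    if fragments_text is not None and config.mode != "partial":
        alignment = Alignment(records=records, aligned=False)

    # 5. MSA sort + optional enumeration
    if tree is not None and alignment is not None:
        alignment = sort_alignment_by_tree(alignment, tree)
        if config.enumerate_leaves:
            tree, alignment = enumerate_leaves(tree, alignment)

    return DomainsResult(
        tree=tree,
        alignment=alignment,
        architectures=architectures,
        metadata=metadata,
    )
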