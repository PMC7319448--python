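"""Shared domain types for phylogeny-anchored genomic-context analysis.

All genomic coordinates are held internally as 0-based half-open
``[start, end)`` intervals; external formats (GFF3, JSON export, rendered
labels) use their own native convention and are converted at the boundary.
Protein-level feature coordinates stay 1-based inclusive, matching HMMER
and domain-database convention.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from skbio import TreeNode

__all__ = [
    "AMINO_ACIDS",
    "GAP",
    "SequenceRecord",
    "Alignment",
    "PhyloTree",
    "FeatureKind",
    "FeatureSource",
    "FeatureHit",
    "DomainArchitecture",
    "Strand",
    "Gene",
    "Replicon",
    "GenomeAnnotation",
    "Neighborhood",
    "GeneCluster",
    "Operon",
    "DistanceMatrix",
    "DomainsConfig",
    "NeighborhoodsConfig",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWYBJOUXZ*"
GAP = "-"

#: A phylogenetic tree: rooted, ordered children, optional branch lengths,
#: leaf names on tips, internal-node names reused as support labels.
PhyloTree = TreeNode


@dataclass
class SequenceRecord:
    """A protein sequence, possibly gapped.

    ``id`` must be non-empty and unique within a dataset; residues are
    normalised to uppercase on construction.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence record id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence record {self.id!r} has no residues")
        self.residues = self.residues.upper()

    @property
    def ungapped(self) -> str:
        return self.residues.replace(GAP, "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """An ordered set of sequences, aligned (equal length, gapped) or not.

    The ``aligned`` flag distinguishes a genuine MSA from a bag of
    equal-length unaligned sequences: a set with no gap character is never
    treated as aligned.
    """

    records: list[SequenceRecord]
    aligned: bool = False

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 records")
        if self.aligned:
            lengths = {len(r) for r in self.records}
            if len(lengths) != 1:
                raise ValueError("aligned records must all have equal length")
            if not any(GAP in r.residues for r in self.records):
                raise ValueError(
                    "equal-length records without gaps are not an alignment; "
                    "pass aligned=False"
                )
        ids = [r.id for r in self.records]
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        if dupes:
            raise ValueError(f"duplicate record ids: {', '.join(dupes)}")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return len(self.records)


class FeatureKind(str, enum.Enum):
    DOMAIN = "domain"
    TRANSMEMBRANE = "transmembrane"
    LOW_COMPLEXITY = "low_complexity"


class FeatureSource(str, enum.Enum):
    PFAM = "pfam"
    CDD = "cdd"
    CUSTOM = "custom"


@dataclass(frozen=True)
class FeatureHit:
    """A scored feature interval on a protein, 1-based inclusive coordinates."""

    protein_id: str
    kind: FeatureKind
    source: FeatureSource
    accession: str
    name: str
    start: int
    end: int
    bit_score: float = 0.0
    evalue: Optional[float] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"feature {self.accession} on {self.protein_id}: "
                f"invalid interval {self.start}..{self.end}"
            )
        if self.evalue is not None and self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap(self, other: "FeatureHit") -> int:
        """Number of shared residues with ``other`` (0 if disjoint)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class DomainArchitecture:
    """The resolved, ordered, non-overlapping feature set of one protein."""

    protein_id: str
    features: list[FeatureHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda h: (h.start, h.end))

    @property
    def domain_accessions(self) -> frozenset[str]:
        """Set (not multiset) of domain accessions; TM/low-complexity excluded."""
        return frozenset(
            h.accession for h in self.features if h.kind is FeatureKind.DOMAIN
        )


class Strand(str, enum.Enum):
    FORWARD = "+"
    REVERSE = "-"


@dataclass
class Gene:
    """An annotated CDS. Coordinates are 0-based half-open on the replicon."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: Strand
    locus_tag: Optional[str] = None
    protein_id: Optional[str] = None
    product: Optional[str] = None
    domain_accessions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Replicon:
    """A chromosome or plasmid with its genes sorted by start."""

    replicon_id: str
    length: Optional[int] = None
    circular: bool = False
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes.sort(key=lambda g: (g.start, g.end))
        seen: set[tuple] = set()
        for g in self.genes:
            key = (g.start, g.end, g.strand)
            if key in seen:
                raise ValueError(
                    f"replicon {self.replicon_id}: duplicate gene placement {key}"
                )
            seen.add(key)
            if self.length is not None and g.end > self.length:
                raise ValueError(
                    f"gene {g.gene_id} extends past end of replicon "
                    f"{self.replicon_id} (length {self.length})"
                )


@dataclass
class GenomeAnnotation:
    """A local gene store: replicon_id -> Replicon. Stand-in for a genome DB."""

    replicons: dict[str, Replicon] = field(default_factory=dict)

    def all_genes(self) -> list[Gene]:
        out: list[Gene] = []
        for rid in self.replicons:
            out.extend(self.replicons[rid].genes)
        return out

    def find_gene(self, identifier: str) -> Gene:
        """Look up a gene by gene_id, protein_id or locus_tag (in that order)."""
        for attr in ("gene_id", "protein_id", "locus_tag"):
            matches = [
                g for g in self.all_genes() if getattr(g, attr) == identifier
            ]
            if len(matches) == 1:
                return matches[0]
            if len(matches) > 1:
                raise KeyError(f"gene identifier {identifier!r} is ambiguous")
        raise KeyError(f"no gene matches identifier {identifier!r}")


@dataclass
class Neighborhood:
    """A query gene plus up to ``window`` flanking genes per side."""

    query_gene_id: str
    genes: list[Gene]
    truncated_left: bool = False
    truncated_right: bool = False
    wrapped: bool = False

    def __post_init__(self) -> None:
        ids = [g.gene_id for g in self.genes]
        if ids.count(self.query_gene_id) != 1:
            raise ValueError(
                f"query {self.query_gene_id} must appear exactly once"
            )
        if len({g.replicon_id for g in self.genes}) != 1:
            raise ValueError("neighborhood genes must share one replicon")

    @property
    def replicon_id(self) -> str:
        return self.genes[0].replicon_id

    @property
    def query(self) -> Gene:
        return next(g for g in self.genes if g.gene_id == self.query_gene_id)


@dataclass
class GeneCluster:
    """A domain-content cluster of genes; ids contiguous from 1."""

    cluster_id: int
    member_gene_ids: list[str]
    domain_signature: frozenset[str]

    def __post_init__(self) -> None:
        if self.cluster_id < 1:
            raise ValueError("cluster ids start at 1")
        if not self.member_gene_ids:
            raise ValueError("cluster must have members")


@dataclass
class Operon:
    """A maximal run of adjacent genes linked by small intergenic gaps."""

    operon_id: int
    replicon_id: str
    strand: Optional[Strand]
    member_gene_ids: list[str]

    def __post_init__(self) -> None:
        if len(self.member_gene_ids) < 2:
            raise ValueError("an operon has at least 2 genes")


@dataclass
class DistanceMatrix:
    """A labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    d: "object"  # numpy (n, n) float array

    def __post_init__(self) -> None:
        import numpy as np

        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix has non-finite entries")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.d < -1e-12).any():
            raise ValueError("distances must be non-negative")


@dataclass
class DomainsConfig:
    """Knobs for the domain-architecture pipeline.

    evalue_max applies to the per-domain independent E-value of domain hits;
    transmembrane and low-complexity features bypass it.
    overlap_fraction_max is the tolerated overlap as a fraction of the
    shorter feature of a pair.
    """

    evalue_max: float = 0.01
    overlap_fraction_max: float = 0.2
    identity_threshold: Optional[float] = None
    enumerate_leaves: bool = False
    skip_features: bool = False
    mode: str = "full"  # "full" | "partial"
    tree_backend: str = "builtin_nj"  # "builtin_nj" | "external"
    aligner_backend: str = "builtin_identity_passthrough"
    kmer_size: int = 3

    def __post_init__(self) -> None:
        if self.evalue_max < 0:
            raise ValueError("evalue_max must be >= 0")
        if not (0.0 <= self.overlap_fraction_max <= 1.0):
            raise ValueError("overlap_fraction_max must be in [0, 1]")
        if self.identity_threshold is not None and not (
            0.0 < self.identity_threshold <= 1.0
        ):
            raise ValueError("identity_threshold must be in (0, 1]")
        if self.mode not in ("full", "partial"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class NeighborhoodsConfig:
    """Knobs for the gene-neighborhood pipeline.

    window is the number of neighboring genes per side of the query;
    nonshared_max is the permitted symmetric-difference size between domain
    sets for two genes to be clustered together; operon_gap_max is the
    inclusive intergenic-distance threshold in bp (default 200).
    """

    window: int = 5
    nonshared_max: int = 0
    operon_gap_max: int = 200
    require_same_strand: bool = True

    def __post_init__(self) -> None:
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.nonshared_max < 0:
            raise ValueError("nonshared_max must be >= 0")
        if self.operon_gap_max < 0:
            raise ValueError("operon_gap_max must be >= 0")
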