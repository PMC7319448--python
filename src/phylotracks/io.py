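"""Readers and writers for the standard formats the toolkit touches.

FASTA and Newick use biopython / scikit-bio underneath; GFF3 CDS extraction,
HMMER3 per-domain tabular output (domtblout) and the generic hits TSV are
parsed directly because the required validation semantics (hard errors on
missing IDs, undefined strand, truncated rows) are part of the contract.
"""

from __future__ import annotations

import io as _io
import re
from typing import Iterable, TextIO, Union

from Bio import SeqIO
from skbio import TreeNode
from skbio.io import NewickFormatError as _SkbioFormatError

from .model import (
    AMINO_ACIDS,
    GAP,
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

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_gff3",
    "read_domtblout",
    "read_hits_tsv",
    "parse_leaf_id",
    "detect_input_type",
]

_VALID_RESIDUES = frozenset(AMINO_ACIDS + GAP)


def _as_stream(source: Union[str, TextIO]) -> TextIO:
    return _io.StringIO(source) if isinstance(source, str) else source


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source: Union[str, TextIO]) -> list[SequenceRecord]:
    """Parse protein FASTA into records.

    The id is the first whitespace-delimited header token; the rest of the
    header becomes the description. Residues are uppercased; the gap
    character '-' is preserved. Duplicate ids and non-amino-acid characters
    are hard errors.
    """
    stream = _as_stream(source)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(stream, "fasta"):
        residues = str(rec.seq).upper()
        for pos, ch in enumerate(residues, start=1):
            if ch not in _VALID_RESIDUES:
                raise ValueError(
                    f"record {rec.id!r}: invalid residue {ch!r} at position {pos}"
                )
        description = rec.description[len(rec.id) :].strip()
        records.append(SequenceRecord(id=rec.id, residues=residues, description=description))
    if not records:
        raise ValueError("no records in FASTA input")
    ids = [r.id for r in records]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise ValueError(f"duplicate ids in FASTA input: {', '.join(dupes)}")
    return records


def write_fasta(records: Iterable[SequenceRecord], line_width: int = 60) -> str:
    """Serialize records to FASTA text, wrapping residues at ``line_width``."""
    records = list(records)
    if not records:
        raise ValueError("cannot write an empty record list")
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    chunks: list[str] = []
    for rec in records:
        header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
        chunks.append(header)
        for i in range(0, len(rec.residues), line_width):
            chunks.append(rec.residues[i : i + line_width])
    return "\n".join(chunks) + "\n"


# ---------------------------------------------------------------------------
# Newick


def read_newick(text: Union[str, TextIO]) -> PhyloTree:
    """Parse a single Newick statement into a tree.

    Child order is preserved as written; internal node labels are kept as
    support values (node names). Underscores in labels are literal (RefSeq
    accessions contain them). Duplicate leaf names are an error.
    """
    if not isinstance(text, str):
        text = text.read()
    stripped = text.strip()
    if not stripped:
        raise ValueError("empty Newick input")
    if not stripped.endswith(";"):
        raise ValueError(
            f"Newick statement must end with ';' (offset {len(stripped)})"
        )
    depth = 0
    for offset, ch in enumerate(stripped):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"unbalanced ')' at offset {offset}")
    if depth != 0:
        raise ValueError(f"unbalanced '(' in Newick input (depth {depth} at end)")
    try:
        tree = TreeNode.read(_io.StringIO(stripped), convert_underscores=False)
    except _SkbioFormatError as exc:  # pragma: no cover - skbio wording varies
        raise ValueError(f"Newick parse error: {exc}") from exc
    names = [tip.name for tip in tree.tips()]
    if len(names) == 0 and tree.name is not None:
        names = [tree.name]
    dupes = sorted({n for n in names if names.count(n) > 1})
    if dupes:
        raise ValueError(f"duplicate leaf names: {', '.join(map(str, dupes))}")
    return tree


_NEEDS_QUOTE = re.compile(r"[\s()\[\]{}:;,']")


def _fmt_label(name: str) -> str:
    if _NEEDS_QUOTE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def write_newick(tree: PhyloTree, precision: int = 6) -> str:
    """Serialize a tree to Newick with branch lengths rounded to ``precision``
    decimal places; deterministic, child order preserved."""

    def fmt(node: TreeNode) -> str:
        if node.is_tip():
            body = _fmt_label(node.name or "")
        else:
            inner = ",".join(fmt(c) for c in node.children)
            label = _fmt_label(node.name) if node.name else ""
            body = f"({inner}){label}"
        if node.length is not None:
            body += f":{round(float(node.length), precision):g}"
        return body

    return fmt(tree) + ";"


# ---------------------------------------------------------------------------
# GFF3


def read_gff3(source: Union[str, TextIO]) -> GenomeAnnotation:
    """Extract CDS features from GFF3 into a genome annotation.

    GFF3 1-based inclusive [start, end] becomes internal 0-based half-open
    [start-1, end). ``##sequence-region`` directives set replicon lengths;
    an ``Is_circular=true`` attribute on a ``region`` feature marks the
    replicon circular. A CDS without an ID, with end < start, or with
    strand '.' is an error.
    """
    stream = _as_stream(source)
    lengths: dict[str, int] = {}
    circular: set[str] = set()
    genes: dict[str, list[Gene]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line:
            continue
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                lengths[parts[1]] = int(parts[3])
            continue
        if line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"GFF3 line {lineno}: expected 9 columns, got {len(cols)}")
        seqid, _src, ftype, start_s, end_s, _score, strand_s, _phase, attr_s = cols
        attrs = _parse_gff3_attributes(attr_s)
        if ftype == "region":
            if attrs.get("Is_circular", "").lower() == "true":
                circular.add(seqid)
            continue
        if ftype != "CDS":
            continue
        start1, end1 = int(start_s), int(end_s)
        if end1 < start1:
            raise ValueError(f"GFF3 line {lineno}: end {end1} before start {start1}")
        gene_id = attrs.get("ID")
        if not gene_id:
            raise ValueError(f"GFF3 line {lineno}: CDS without ID attribute")
        if strand_s == "+":
            strand = Strand.FORWARD
        elif strand_s == "-":
            strand = Strand.REVERSE
        else:
            raise ValueError(
                f"GFF3 line {lineno}: CDS {gene_id} has undefined strand {strand_s!r}"
            )
        genes.setdefault(seqid, []).append(
            Gene(
                gene_id=gene_id,
                replicon_id=seqid,
                start=start1 - 1,
                end=end1,
                strand=strand,
                locus_tag=attrs.get("locus_tag"),
                protein_id=attrs.get("protein_id"),
                product=attrs.get("product"),
            )
        )
    replicons = {}
    for rid in sorted(set(genes) | set(lengths)):
        replicons[rid] = Replicon(
            replicon_id=rid,
            length=lengths.get(rid),
            circular=rid in circular,
            genes=genes.get(rid, []),
        )
    return GenomeAnnotation(replicons=replicons)


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        key, _, value = item.partition("=")
        attrs[key] = _gff3_unescape(value)
    return attrs


def _gff3_unescape(value: str) -> str:
    return re.sub(r"%([0-9A-Fa-f]{2})", lambda m: chr(int(m.group(1), 16)), value)


def gene_to_gff3_coords(gene: Gene) -> tuple[int, int]:
    """Convert internal half-open coordinates back to GFF3 1-based inclusive."""
    return gene.start + 1, gene.end


# ---------------------------------------------------------------------------
# HMMER domtblout and generic hits TSV


def read_domtblout(source: Union[str, TextIO]) -> list[FeatureHit]:
    """Parse HMMER3 per-domain tabular output.

    Envelope coordinates (columns 20-21) define feature extent; the
    per-domain independent E-value (column 13) is the hit's E-value and the
    per-domain bit score (column 14) its score. Query accession/name map to
    the feature accession/name; all hits are domain-kind.
    """
    stream = _as_stream(source)
    hits: list[FeatureHit] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 23:
            raise ValueError(
                f"domtblout line {lineno}: expected >= 23 columns, got {len(cols)}"
            )
        target_name = cols[0]
        query_name, query_acc = cols[3], cols[4]
        i_evalue, dom_score = float(cols[12]), float(cols[13])
        env_from, env_to = int(cols[19]), int(cols[20])
        accession = query_acc if query_acc != "-" else query_name
        hits.append(
            FeatureHit(
                protein_id=target_name,
                kind=FeatureKind.DOMAIN,
                source=FeatureSource.PFAM,
                accession=accession,
                name=query_name,
                start=env_from,
                end=env_to,
                bit_score=dom_score,
                evalue=i_evalue,
            )
        )
    return hits


_TSV_COLUMNS = [
    "protein_id",
    "kind",
    "source",
    "accession",
    "name",
    "start",
    "end",
    "bit_score",
    "evalue",
]


def read_hits_tsv(source: Union[str, TextIO]) -> list[FeatureHit]:
    """Parse the generic tab-separated hits table (header required).

    Columns: protein_id, kind, source, accession, name, start, end,
    bit_score, evalue. An empty evalue field means "not applicable"
    (e.g. transmembrane predictions).
    """
    stream = _as_stream(source)
    lines = [ln.rstrip("\n") for ln in stream if ln.strip()]
    if not lines:
        raise ValueError("empty hits TSV")
    header = lines[0].split("\t")
    if header != _TSV_COLUMNS:
        raise ValueError(
            f"hits TSV header must be {_TSV_COLUMNS}, got {header}"
        )
    hits: list[FeatureHit] = []
    for lineno, line in enumerate(lines[1:], start=2):
        cols = line.split("\t")
        if len(cols) != len(_TSV_COLUMNS):
            raise ValueError(f"hits TSV line {lineno}: wrong column count")
        row = dict(zip(_TSV_COLUMNS, cols))
        hits.append(
            FeatureHit(
                protein_id=row["protein_id"],
                kind=FeatureKind(row["kind"]),
                source=FeatureSource(row["source"]),
                accession=row["accession"],
                name=row["name"],
                start=int(row["start"]),
                end=int(row["end"]),
                bit_score=float(row["bit_score"]) if row["bit_score"] else 0.0,
                evalue=float(row["evalue"]) if row["evalue"] else None,
            )
        )
    return hits


def write_hits_tsv(hits: Iterable[FeatureHit]) -> str:
    rows = ["\t".join(_TSV_COLUMNS)]
    for h in hits:
        rows.append(
            "\t".join(
                [
                    h.protein_id,
                    h.kind.value,
                    h.source.value,
                    h.accession,
                    h.name,
                    str(h.start),
                    str(h.end),
                    repr(h.bit_score),
                    repr(h.evalue) if h.evalue is not None else "",
                ]
            )
        )
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Leaf-name identifier extraction and input-type detection

#: Versioned accession with an internal underscore, e.g. WP_011030745.1.
_ACCESSION_RE = re.compile(r"^[A-Za-z]+_[A-Za-z0-9]+\.\d+")
_SOFT_DELIMS = re.compile(r"[ |/]")


def parse_leaf_id(leaf_name: str) -> str:
    """Extract the protein identifier prefix from a tree leaf name.

    Identifiers are separated from the rest of the name by an underscore,
    a space, a forward slash or a vertical bar. Because RefSeq accessions
    themselves contain an underscore, a leading versioned accession
    (``XX_…​.N``) is recognised first and kept whole; otherwise the name is
    split at the first space/'|'/'/', and only then at the first '_'.
    """
    if not leaf_name:
        raise ValueError("empty leaf name")
    m = _ACCESSION_RE.match(leaf_name)
    if m:
        return m.group(0)
    m = _SOFT_DELIMS.search(leaf_name)
    if m:
        head = leaf_name[: m.start()]
        if head:
            return head
    if "_" in leaf_name:
        head = leaf_name.split("_", 1)[0]
        if head:
            return head
    return leaf_name


_ID_TOKEN_RE = re.compile(r"^[A-Za-z0-9._|-]+$")


def detect_input_type(text: str) -> str:
    """Classify raw input text as 'newick', 'sequences', 'alignment' or 'id_list'.

    Newick: starts with '(' and parses. FASTA: starts with '>'; it is an
    alignment iff all residue strings have equal length AND at least one gap
    character is present. Otherwise newline-separated bare tokens form an
    id_list. Anything else is unrecognized.
    """
    stripped = text.strip()
    if not stripped:
        raise ValueError("empty input")
    if stripped.startswith("("):
        read_newick(stripped)  # raises on malformed input
        return "newick"
    if stripped.startswith(">"):
        records = read_fasta(stripped)
        lengths = {len(r) for r in records}
        has_gap = any(GAP in r.residues for r in records)
        if len(records) >= 2 and len(lengths) == 1 and has_gap:
            return "alignment"
        return "sequences"
    tokens = [ln.strip() for ln in stripped.splitlines() if ln.strip()]
    if tokens and all(_ID_TOKEN_RE.match(t) for t in tokens):
        return "id_list"
    raise ValueError("unrecognized input: not Newick, FASTA or an identifier list")
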