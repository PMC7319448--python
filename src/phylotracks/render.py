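"""Tree + per-leaf feature tracks -> deterministic JSON and SVG.

The SVG is a static picture: a rectangular phylogram on the left, one row
per leaf, and on the right either a domain-architecture glyph row (scaled
protein ruler with feature boxes) or a gene-neighborhood row (gene arrows;
fill color = domain-content cluster, border color = operon, thick border =
query gene). Every glyph carries a ``<title>`` element with the underlying
record's details, the static analogue of an interactive tooltip. Output is
byte-identical across runs on identical input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Union
from xml.sax.saxutils import escape, quoteattr

from . import io as ptio
from .domains import DomainsResult
from .model import FeatureKind, GeneCluster, Operon, PhyloTree, Strand
from .neighborhoods import NeighborhoodsResult
from .schema import validate_document

__all__ = [
    "PALETTE",
    "NEUTRAL_COLOR",
    "RenderConfig",
    "RenderModel",
    "order_leaves",
    "assign_colors",
    "assemble_render_model",
    "render_svg",
    "export_json",
]

#: Fixed 20-entry cyclic palette (fill colors for clusters, border colors
#: for operons). After exhaustion colors repeat with a hatch flag set.
PALETTE = [
    "#1f77b4", "#ff7f0e", "#2ca02c", "#d62728", "#9467bd",
    "#8c564b", "#e377c2", "#7f7f7f", "#bcbd22", "#17becf",
    "#aec7e8", "#ffbb78", "#98df8a", "#ff9896", "#c5b0d5",
    "#c49c94", "#f7b6d2", "#dbdb8d", "#9edae5", "#393b79",
]

#: Reserved color for domain-less (unclustered) genes.
NEUTRAL_COLOR = "#d9d9d9"

_KIND_COLORS = {
    FeatureKind.DOMAIN: None,  # palette by accession
    FeatureKind.TRANSMEMBRANE: "#555555",
    FeatureKind.LOW_COMPLEXITY: "#cccccc",
}


@dataclass
class RenderConfig:
    ladderize: bool = False
    row_height: float = 28.0
    tree_width: float = 180.0
    track_width: float = 560.0
    label_width: float = 170.0
    scale: Optional[float] = None  # px per residue / per bp; None = auto
    margin: float = 12.0


def order_leaves(tree: PhyloTree, ladderize: bool = False) -> list[str]:
    """Depth-first leaf order, children in stored order.

    With ``ladderize`` children are sorted by subtree leaf count ascending
    (ties broken by lexicographically smallest contained leaf name) before
    traversal.
    """
    def walk(node) -> list[str]:
        if node.is_tip():
            return [node.name]
        kids = list(node.children)
        if ladderize:
            kids = sorted(kids, key=_ladder_key)
        out: list[str] = []
        for c in kids:
            out.extend(walk(c))
        return out

    return walk(tree)


def _ladder_key(node) -> tuple[int, str]:
    if node.is_tip():
        return (1, node.name)
    leaves = [t.name for t in node.tips()]
    return (len(leaves), min(leaves))


@dataclass
class ColorAssignment:
    fill: str
    hatch: bool = False


def assign_colors(
    clusters: list[GeneCluster],
    operons: list[Operon],
    display_gene_order: list[str],
) -> dict[str, dict[int, ColorAssignment]]:
    """Deterministic palette for clusters (fills) and operons (borders).

    Ids are ranked by the first occurrence of any member in
    ``display_gene_order`` (leaves top-to-bottom, genes left-to-right) and
    take palette entries in that order, cycling with a hatch flag once the
    20 colors are exhausted. Unranked ids (no member displayed) follow in
    id order.
    """
    pos = {gid: i for i, gid in enumerate(display_gene_order)}

    def ranked(items, members_of):
        def key(item):
            ps = [pos[g] for g in members_of(item) if g in pos]
            return (min(ps) if ps else 1 << 30, item)
        return sorted(items, key=lambda it: key(it))

    palette: dict[str, dict[int, ColorAssignment]] = {"cluster": {}, "operon": {}}
    cl_by_id = {c.cluster_id: c for c in clusters}
    for rank, cid in enumerate(
        ranked(cl_by_id, lambda cid: cl_by_id[cid].member_gene_ids)
    ):
        palette["cluster"][cid] = ColorAssignment(
            fill=PALETTE[rank % len(PALETTE)], hatch=rank >= len(PALETTE)
        )
    op_by_id = {o.operon_id: o for o in operons}
    for rank, oid in enumerate(
        ranked(op_by_id, lambda oid: op_by_id[oid].member_gene_ids)
    ):
        palette["operon"][oid] = ColorAssignment(
            fill=PALETTE[rank % len(PALETTE)], hatch=rank >= len(PALETTE)
        )
    return palette


# ---------------------------------------------------------------------------
# Render model


@dataclass
class FeatureGlyph:
    accession: str
    name: str
    kind: str
    start: int
    end: int
    color: str
    tooltip: str


@dataclass
class GeneGlyph:
    gene_id: str
    start: int  # bp offset within the track, 0-based
    end: int
    strand: str
    fill: str
    hatch: bool
    border: str
    thick: bool
    tooltip: str


@dataclass
class Track:
    kind: str  # "architecture" | "neighborhood" | "empty"
    length: int = 0  # residues or bp spanned
    features: list[FeatureGlyph] = field(default_factory=list)
    genes: list[GeneGlyph] = field(default_factory=list)


@dataclass
class RenderModel:
    tree: Optional[PhyloTree]
    leaf_order: list[str]
    tracks: dict[str, Track]
    palette: dict[str, dict[int, ColorAssignment]]
    config: RenderConfig
    metadata: dict = field(default_factory=dict)


def assemble_render_model(
    result: Union[DomainsResult, NeighborhoodsResult],
    config: Optional[RenderConfig] = None,
) -> RenderModel:
    """Join a pipeline result's tree with one visual track per leaf.

    Tracks are keyed by leaf name; leaf names resolve to protein/gene data
    through ``parse_leaf_id``. A leaf with no matching data gets an
    explicit empty track and a warning in the model metadata.
    """
    config = config or RenderConfig()
    warnings: list[str] = []
    if result.tree is not None:
        leaf_order = order_leaves(result.tree, ladderize=config.ladderize)
    elif isinstance(result, NeighborhoodsResult):
        leaf_order = [
            nb.query.protein_id or nb.query_gene_id for nb in result.neighborhoods
        ]
    else:
        leaf_order = sorted(result.architectures)

    if isinstance(result, DomainsResult):
        tracks = _architecture_tracks(result, leaf_order, warnings)
        palette = {"cluster": {}, "operon": {}}
    else:
        tracks, palette = _neighborhood_tracks(result, leaf_order, warnings)

    return RenderModel(
        tree=result.tree,
        leaf_order=leaf_order,
        tracks=tracks,
        palette=palette,
        config=config,
        metadata={"warnings": warnings},
    )


def _architecture_tracks(
    result: DomainsResult, leaf_order: list[str], warnings: list[str]
) -> dict[str, Track]:
    # stable per-figure domain colors, by first appearance in leaf order
    acc_colors: dict[str, str] = {}
    lengths: dict[str, int] = {}
    if result.alignment is not None:
        for rec in result.alignment.records:
            lengths[ptio.parse_leaf_id(rec.id)] = len(rec.ungapped)
    tracks: dict[str, Track] = {}
    for leaf in leaf_order:
        pid = ptio.parse_leaf_id(leaf)
        arch = result.architectures.get(pid)
        if arch is None:
            tracks[leaf] = Track(kind="empty")
            warnings.append(f"no architecture for leaf {leaf!r}")
            continue
        length = max(
            [lengths.get(pid, 0)] + [f.end for f in arch.features]
        )
        glyphs = []
        for f in arch.features:
            if f.kind is FeatureKind.DOMAIN:
                if f.accession not in acc_colors:
                    acc_colors[f.accession] = PALETTE[len(acc_colors) % len(PALETTE)]
                color = acc_colors[f.accession]
            else:
                color = _KIND_COLORS[f.kind]
            glyphs.append(
                FeatureGlyph(
                    accession=f.accession,
                    name=f.name,
                    kind=f.kind.value,
                    start=f.start,
                    end=f.end,
                    color=color,
                    tooltip=f"{f.accession} {f.name} {f.start}-{f.end}",
                )
            )
        tracks[leaf] = Track(kind="architecture", length=length, features=glyphs)
    return tracks


def _neighborhood_tracks(
    result: NeighborhoodsResult, leaf_order: list[str], warnings: list[str]
):
    nb_by_pid = {
        (nb.query.protein_id or nb.query_gene_id): nb for nb in result.neighborhoods
    }
    # display order of genes: leaves top-to-bottom, genes left-to-right
    display_gene_order: list[str] = []
    for leaf in leaf_order:
        nb = nb_by_pid.get(ptio.parse_leaf_id(leaf))
        if nb is not None:
            display_gene_order.extend(g.gene_id for g in nb.genes)
    palette = assign_colors(result.clusters, result.operons, display_gene_order)
    cluster_of = {
        gid: c.cluster_id for c in result.clusters for gid in c.member_gene_ids
    }
    operon_of = {
        gid: o.operon_id for o in result.operons for gid in o.member_gene_ids
    }
    tracks: dict[str, Track] = {}
    for leaf in leaf_order:
        pid = ptio.parse_leaf_id(leaf)
        nb = nb_by_pid.get(pid)
        if nb is None:
            tracks[leaf] = Track(kind="empty")
            warnings.append(f"no neighborhood for leaf {leaf!r}")
            continue
        origin = min(g.start for g in nb.genes)
        span = max(g.end for g in nb.genes) - origin
        glyphs = []
        for g in nb.genes:
            cid = cluster_of.get(g.gene_id)
            oid = operon_of.get(g.gene_id)
            fill = palette["cluster"][cid] if cid is not None else None
            border = palette["operon"][oid].fill if oid is not None else "#333333"
            domains = ",".join(sorted(g.domain_accessions)) or "none"
            glyphs.append(
                GeneGlyph(
                    gene_id=g.gene_id,
                    start=g.start - origin,
                    end=g.end - origin,
                    strand=g.strand.value,
                    fill=fill.fill if fill else NEUTRAL_COLOR,
                    hatch=fill.hatch if fill else False,
                    border=border,
                    thick=(g.gene_id == nb.query_gene_id),
                    tooltip=(
                        f"{g.gene_id} [{g.start + 1}-{g.end} {g.strand.value}] "
                        f"product={g.product or '?'} domains={domains} "
                        f"cluster={cid if cid is not None else '-'} "
                        f"operon={oid if oid is not None else '-'}"
                    ),
                )
            )
        tracks[leaf] = Track(kind="neighborhood", length=span, genes=glyphs)
    return tracks, palette


# ---------------------------------------------------------------------------
# SVG


def render_svg(model: RenderModel) -> str:
    """Serialize a render model to standalone SVG text (deterministic)."""
    cfg = model.config
    rows = model.leaf_order or []
    height = 2 * cfg.margin + max(1, len(rows)) * cfg.row_height
    width = cfg.margin * 3 + cfg.tree_width + cfg.label_width + cfg.track_width

    # unit scale shared across the figure (px per residue or per bp)
    max_len = max((t.length for t in model.tracks.values()), default=0)
    unit = cfg.scale if cfg.scale is not None else (
        cfg.track_width / max_len if max_len else 1.0
    )

    out: list[str] = []
    out.append('<?xml version="1.0" encoding="UTF-8"?>')
    out.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'width="{width:g}" height="{height:g}" '
        f'viewBox="0 0 {width:g} {height:g}">'
    )
    out.append(
        "<defs><pattern id=\"hatch\" width=\"6\" height=\"6\" "
        "patternUnits=\"userSpaceOnUse\" patternTransform=\"rotate(45)\">"
        "<line x1=\"0\" y1=\"0\" x2=\"0\" y2=\"6\" stroke=\"#ffffff\" "
        "stroke-width=\"2\"/></pattern></defs>"
    )

    leaf_y = {
        leaf: cfg.margin + (i + 0.5) * cfg.row_height for i, leaf in enumerate(rows)
    }
    if model.tree is not None and rows:
        out.extend(_tree_lines(model.tree, leaf_y, cfg))

    x0 = cfg.margin * 2 + cfg.tree_width + cfg.label_width
    for leaf in rows:
        y = leaf_y[leaf]
        track = model.tracks.get(leaf, Track(kind="empty"))
        out.append(f'<g class="leaf-row" id={quoteattr("row-" + leaf)}>')
        out.append(
            f'<text x="{cfg.margin + cfg.tree_width + 4:g}" y="{y + 4:g}" '
            f'font-family="monospace" font-size="11">{escape(leaf)}</text>'
        )
        if track.kind == "architecture":
            out.extend(_architecture_row(track, x0, y, unit))
        elif track.kind == "neighborhood":
            out.extend(_neighborhood_row(track, x0, y, unit))
        out.append("</g>")
    out.append("</svg>")
    return "\n".join(out) + "\n"


def _tree_lines(tree: PhyloTree, leaf_y: dict[str, float], cfg: RenderConfig):
    # x by cumulative branch length (unit lengths when absent)
    depth: dict[int, float] = {}
    ypos: dict[int, float] = {}

    def set_depth(node, acc: float) -> None:
        depth[id(node)] = acc
        for c in node.children:
            set_depth(c, acc + (c.length if c.length is not None else 1.0))

    set_depth(tree, 0.0)
    max_depth = max(depth.values()) or 1.0
    sx = cfg.tree_width / max_depth

    def set_y(node) -> float:
        if node.is_tip():
            ypos[id(node)] = leaf_y.get(node.name, cfg.margin)
        else:
            ys = [set_y(c) for c in node.children]
            ypos[id(node)] = sum(ys) / len(ys)
        return ypos[id(node)]

    set_y(tree)
    lines: list[str] = ['<g class="tree" stroke="#000000" stroke-width="1">']

    def emit(node) -> None:
        x = cfg.margin + depth[id(node)] * sx
        for c in node.children:
            cx = cfg.margin + depth[id(c)] * sx
            cy = ypos[id(c)]
            lines.append(
                f'<line x1="{x:.2f}" y1="{cy:.2f}" x2="{cx:.2f}" y2="{cy:.2f}"/>'
            )
            emit(c)
        if node.children:
            ys = [ypos[id(c)] for c in node.children]
            lines.append(
                f'<line x1="{x:.2f}" y1="{min(ys):.2f}" '
                f'x2="{x:.2f}" y2="{max(ys):.2f}"/>'
            )

    emit(tree)
    lines.append("</g>")
    return lines


def _architecture_row(track: Track, x0: float, y: float, unit: float):
    h = 12.0
    out = [
        f'<line class="ruler" x1="{x0:.2f}" y1="{y:.2f}" '
        f'x2="{x0 + track.length * unit:.2f}" y2="{y:.2f}" '
        'stroke="#999999" stroke-width="1"/>'
    ]
    for f in track.features:
        x = x0 + (f.start - 1) * unit
        w = (f.end - f.start + 1) * unit
        ry = 5 if f.kind == "domain" else 2
        out.append(
            f'<rect class="feature" x="{x:.2f}" y="{y - h / 2:.2f}" '
            f'width="{w:.2f}" height="{h:.2f}" rx="{ry}" '
            f'fill="{f.color}" stroke="#333333" stroke-width="0.8">'
            f"<title>{escape(f.tooltip)}</title></rect>"
        )
    return out


def _neighborhood_row(track: Track, x0: float, y: float, unit: float):
    h = 14.0
    out: list[str] = []
    for g in track.genes:
        x1 = x0 + g.start * unit
        x2 = x0 + g.end * unit
        head = min(6.0, (x2 - x1) * 0.4)
        if g.strand == "+":
            pts = [
                (x1, y - h / 2), (x2 - head, y - h / 2), (x2, y),
                (x2 - head, y + h / 2), (x1, y + h / 2),
            ]
        else:
            pts = [
                (x2, y - h / 2), (x1 + head, y - h / 2), (x1, y),
                (x1 + head, y + h / 2), (x2, y + h / 2),
            ]
        pts_s = " ".join(f"{px:.2f},{py:.2f}" for px, py in pts)
        sw = 3.0 if g.thick else 1.2
        out.append(
            f'<polygon class="gene" points="{pts_s}" fill="{g.fill}" '
            f'stroke="{g.border}" stroke-width="{sw:g}">'
            f"<title>{escape(g.tooltip)}</title></polygon>"
        )
        if g.hatch:
            out.append(
                f'<polygon class="gene-hatch" points="{pts_s}" '
                f'fill="url(#hatch)" stroke="none"/>'
            )
    return out


# ---------------------------------------------------------------------------
# JSON export


def export_json(result: Union[DomainsResult, NeighborhoodsResult]) -> str:
    """Serialize a pipeline result to schema-validated JSON text.

    Keys are sorted and the document carries a versioned ``schema`` field;
    the ``parameters`` block records every applied parameter including
    defaults. Gene coordinates are exported 1-based inclusive.
    """
    if isinstance(result, DomainsResult):
        doc = _domains_document(result)
    else:
        doc = _neighborhoods_document(result)
    validate_document(doc)
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"


def _feature_dict(f) -> dict:
    return {
        "kind": f.kind.value,
        "source": f.source.value,
        "accession": f.accession,
        "name": f.name,
        "start": f.start,
        "end": f.end,
        "bit_score": f.bit_score,
        "evalue": f.evalue,
    }


def _domains_document(result: DomainsResult) -> dict:
    return {
        "schema": "phylotracks-domains-v1",
        "parameters": result.metadata,
        "tree": ptio.write_newick(result.tree) if result.tree is not None else None,
        "alignment": (
            [
                {"id": r.id, "residues": r.residues, "description": r.description}
                for r in result.alignment.records
            ]
            if result.alignment is not None
            else None
        ),
        "architectures": [
            {
                "protein_id": pid,
                "features": [_feature_dict(f) for f in arch.features],
            }
            for pid, arch in sorted(result.architectures.items())
        ],
    }


def _neighborhoods_document(result: NeighborhoodsResult) -> dict:
    cluster_of = {
        gid: c.cluster_id for c in result.clusters for gid in c.member_gene_ids
    }
    operon_of = {
        gid: o.operon_id for o in result.operons for gid in o.member_gene_ids
    }
    queries = []
    for nb in result.neighborhoods:
        queries.append(
            {
                "query_gene_id": nb.query_gene_id,
                "replicon_id": nb.replicon_id,
                "truncated_left": nb.truncated_left,
                "truncated_right": nb.truncated_right,
                "wrapped": nb.wrapped,
                "genes": [
                    {
                        "gene_id": g.gene_id,
                        "locus_tag": g.locus_tag,
                        "protein_id": g.protein_id,
                        "start": g.start + 1,  # 1-based inclusive in export
                        "end": g.end,
                        "strand": g.strand.value,
                        "product": g.product,
                        "domain_accessions": sorted(g.domain_accessions),
                        "cluster_id": cluster_of.get(g.gene_id),
                        "operon_id": operon_of.get(g.gene_id),
                    }
                    for g in nb.genes
                ],
            }
        )
    return {
        "schema": "phylotracks-neighborhoods-v1",
        "parameters": result.metadata,
        "tree": ptio.write_newick(result.tree) if result.tree is not None else None,
        "queries": queries,
        "clusters": [
            {
                "cluster_id": c.cluster_id,
                "member_gene_ids": list(c.member_gene_ids),
                "domain_signature": sorted(c.domain_signature),
            }
            for c in result.clusters
        ],
        "operons": [
            {
                "operon_id": o.operon_id,
                "replicon_id": o.replicon_id,
                "strand": o.strand.value if o.strand is not None else None,
                "member_gene_ids": list(o.member_gene_ids),
            }
            for o in result.operons
        ],
    }
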