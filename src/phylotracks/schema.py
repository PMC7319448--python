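"""JSON export document models and validation.

The export documents are defined as pydantic models; ``validate_document``
checks a dict against the model matching its ``schema`` field. JSON Schema
renderings of the same models are shipped under ``phylotracks/schemas/``
(see ``dump_schemas``) so downstream consumers can validate without
importing this package.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "DomainsDocument",
    "NeighborhoodsDocument",
    "validate_document",
    "dump_schemas",
]


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FeatureDoc(_Model):
    kind: Literal["domain", "transmembrane", "low_complexity"]
    source: Literal["pfam", "cdd", "custom"]
    accession: str
    name: str
    start: int = Field(ge=1)
    end: int = Field(ge=1)
    bit_score: float
    evalue: Optional[float] = None


class ArchitectureDoc(_Model):
    protein_id: str
    features: list[FeatureDoc]


class AlignmentRowDoc(_Model):
    id: str
    residues: str
    description: str = ""


class DomainsDocument(_Model):
    schema_: Literal["phylotracks-domains-v1"] = Field(alias="schema")
    parameters: dict
    tree: Optional[str]
    alignment: Optional[list[AlignmentRowDoc]]
    architectures: list[ArchitectureDoc]


class GeneDoc(_Model):
    gene_id: str
    locus_tag: Optional[str]
    protein_id: Optional[str]
    start: int = Field(ge=1, description="1-based inclusive")
    end: int = Field(ge=1)
    strand: Literal["+", "-"]
    product: Optional[str]
    domain_accessions: list[str]
    cluster_id: Optional[int]
    operon_id: Optional[int]


class NeighborhoodDoc(_Model):
    query_gene_id: str
    replicon_id: str
    truncated_left: bool
    truncated_right: bool
    wrapped: bool
    genes: list[GeneDoc]


class ClusterDoc(_Model):
    cluster_id: int = Field(ge=1)
    member_gene_ids: list[str] = Field(min_length=1)
    domain_signature: list[str]


class OperonDoc(_Model):
    operon_id: int = Field(ge=1)
    replicon_id: str
    strand: Optional[Literal["+", "-"]]
    member_gene_ids: list[str] = Field(min_length=2)


class NeighborhoodsDocument(_Model):
    schema_: Literal["phylotracks-neighborhoods-v1"] = Field(alias="schema")
    parameters: dict
    tree: Optional[str]
    queries: list[NeighborhoodDoc]
    clusters: list[ClusterDoc]
    operons: list[OperonDoc]


_DOCUMENTS = {
    "phylotracks-domains-v1": DomainsDocument,
    "phylotracks-neighborhoods-v1": NeighborhoodsDocument,
}


def validate_document(doc: dict) -> None:
    """Validate an export document against its declared schema; raises
    pydantic.ValidationError (or KeyError for an unknown schema id)."""
    model = _DOCUMENTS[doc["schema"]]
    model.model_validate(doc)


def shipped_schema(schema_id: str) -> dict:
    """Load the JSON Schema file shipped in the package for ``schema_id``."""
    name = schema_id + ".json"
    with resources.files("phylotracks.schemas").joinpath(name).open() as fh:
        return json.load(fh)


def generated_schema(schema_id: str) -> dict:
    """JSON Schema generated from the pydantic model, with its $id set."""
    schema = _DOCUMENTS[schema_id].model_json_schema()
    schema["$id"] = f"https://example.org/phylotracks/schemas/{schema_id}.json"
    return schema


def dump_schemas(out_dir) -> list[str]:
    """Write one JSON Schema file per document model into ``out_dir``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for schema_id in _DOCUMENTS:
        path = out / f"{schema_id}.json"
        path.write_text(
            json.dumps(generated_schema(schema_id), sort_keys=True, indent=2) + "\n"
        )
        written.append(str(path))
    return written
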