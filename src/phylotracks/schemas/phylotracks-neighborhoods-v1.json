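{
  "$defs": {
    "ClusterDoc": {
      "additionalProperties": false,
      "properties": {
        "cluster_id": {
          "minimum": 1,
          "title": "Cluster Id",
          "type": "integer"
        },
        "domain_signature": {
          "items": {
            "type": "string"
          },
          "title": "Domain Signature",
          "type": "array"
        },
        "member_gene_ids": {
          "items": {
            "type": "string"
          },
          "minItems": 1,
          "title": "Member Gene Ids",
          "type": "array"
        }
      },
      "required": [
        "cluster_id",
        "member_gene_ids",
        "domain_signature"
      ],
      "title": "ClusterDoc",
      "type": "object"
    },
    "GeneDoc": {
      "additionalProperties": false,
      "properties": {
        "cluster_id": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "title": "Cluster Id"
        },
        "domain_accessions": {
          "items": {
            "type": "string"
          },
          "title": "Domain Accessions",
          "type": "array"
        },
        "end": {
          "minimum": 1,
          "title": "End",
          "type": "integer"
        },
        "gene_id": {
          "title": "Gene Id",
          "type": "string"
        },
        "locus_tag": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "title": "Locus Tag"
        },
        "operon_id": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "title": "Operon Id"
        },
        "product": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "title": "Product"
        },
        "protein_id": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "title": "Protein Id"
        },
        "start": {
          "description": "1-based inclusive",
          "minimum": 1,
          "title": "Start",
          "type": "integer"
        },
        "strand": {
          "enum": [
            "+",
            "-"
          ],
          "title": "Strand",
          "type": "string"
        }
      },
      "required": [
        "gene_id",
        "locus_tag",
        "protein_id",
        "start",
        "end",
        "strand",
        "product",
        "domain_accessions",
        "cluster_id",
        "operon_id"
      ],
      "title": "GeneDoc",
      "type": "object"
    },
    "NeighborhoodDoc": {
      "additionalProperties": false,
      "properties": {
        "genes": {
          "items": {
            "$ref": "#/$defs/GeneDoc"
          },
          "title": "Genes",
          "type": "array"
        },
        "query_gene_id": {
          "title": "Query Gene Id",
          "type": "string"
        },
        "replicon_id": {
          "title": "Replicon Id",
          "type": "string"
        },
        "truncated_left": {
          "title": "Truncated Left",
          "type": "boolean"
        },
        "truncated_right": {
          "title": "Truncated Right",
          "type": "boolean"
        },
        "wrapped": {
          "title": "Wrapped",
          "type": "boolean"
        }
      },
      "required": [
        "query_gene_id",
        "replicon_id",
        "truncated_left",
        "truncated_right",
        "wrapped",
        "genes"
      ],
      "title": "NeighborhoodDoc",
      "type": "object"
    },
    "OperonDoc": {
      "additionalProperties": false,
      "properties": {
        "member_gene_ids": {
          "items": {
            "type": "string"
          },
          "minItems": 2,
          "title": "Member Gene Ids",
          "type": "array"
        },
        "operon_id": {
          "minimum": 1,
          "title": "Operon Id",
          "type": "integer"
        },
        "replicon_id": {
          "title": "Replicon Id",
          "type": "string"
        },
        "strand": {
          "anyOf": [
            {
              "enum": [
                "+",
                "-"
              ],
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "title": "Strand"
        }
      },
      "required": [
        "operon_id",
        "replicon_id",
        "strand",
        "member_gene_ids"
      ],
      "title": "OperonDoc",
      "type": "object"
    }
  },
  "$id": "https://example.org/phylotracks/schemas/phylotracks-neighborhoods-v1.json",
  "additionalProperties": false,
  "properties": {
    "clusters": {
      "items": {
        "$ref": "#/$defs/ClusterDoc"
      },
      "title": "Clusters",
      "type": "array"
    },
    "operons": {
      "items": {
        "$ref": "#/$defs/OperonDoc"
      },
      "title": "Operons",
      "type": "array"
    },
    "parameters": {
      "additionalProperties": true,
      "title": "Parameters",
      "type": "object"
    },
    "queries": {
      "items": {
        "$ref": "#/$defs/NeighborhoodDoc"
      },
      "title": "Queries",
      "type": "array"
    },
    "schema": {
      "const": "phylotracks-neighborhoods-v1",
      "title": "Schema",
      "type": "string"
    },
    "tree": {
      "anyOf": [
        {
          "type": "string"
        },
        {
          "type": "null"
        }
      ],
      "title": "Tree"
    }
  },
  "required": [
    "schema",
    "parameters",
    "tree",
    "queries",
    "clusters",
    "operons"
  ],
  "title": "NeighborhoodsDocument",
  "type": "object"
}
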