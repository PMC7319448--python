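{
  "$defs": {
    "AlignmentRowDoc": {
      "additionalProperties": false,
      "properties": {
        "description": {
          "default": "",
          "title": "Description",
          "type": "string"
        },
        "id": {
          "title": "Id",
          "type": "string"
        },
        "residues": {
          "title": "Residues",
          "type": "string"
        }
      },
      "required": [
        "id",
        "residues"
      ],
      "title": "AlignmentRowDoc",
      "type": "object"
    },
    "ArchitectureDoc": {
      "additionalProperties": false,
      "properties": {
        "features": {
          "items": {
            "$ref": "#/$defs/FeatureDoc"
          },
          "title": "Features",
          "type": "array"
        },
        "protein_id": {
          "title": "Protein Id",
          "type": "string"
        }
      },
      "required": [
        "protein_id",
        "features"
      ],
      "title": "ArchitectureDoc",
      "type": "object"
    },
    "FeatureDoc": {
      "additionalProperties": false,
      "properties": {
        "accession": {
          "title": "Accession",
          "type": "string"
        },
        "bit_score": {
          "title": "Bit Score",
          "type": "number"
        },
        "end": {
          "minimum": 1,
          "title": "End",
          "type": "integer"
        },
        "evalue": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Evalue"
        },
        "kind": {
          "enum": [
            "domain",
            "transmembrane",
            "low_complexity"
          ],
          "title": "Kind",
          "type": "string"
        },
        "name": {
          "title": "Name",
          "type": "string"
        },
        "source": {
          "enum": [
            "pfam",
            "cdd",
            "custom"
          ],
          "title": "Source",
          "type": "string"
        },
        "start": {
          "minimum": 1,
          "title": "Start",
          "type": "integer"
        }
      },
      "required": [
        "kind",
        "source",
        "accession",
        "name",
        "start",
        "end",
        "bit_score"
      ],
      "title": "FeatureDoc",
      "type": "object"
    }
  },
  "$id": "https://example.org/phylotracks/schemas/phylotracks-domains-v1.json",
  "additionalProperties": false,
  "properties": {
    "alignment": {
      "anyOf": [
        {
          "items": {
            "$ref": "#/$defs/AlignmentRowDoc"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "title": "Alignment"
    },
    "architectures": {
      "items": {
        "$ref": "#/$defs/ArchitectureDoc"
      },
      "title": "Architectures",
      "type": "array"
    },
    "parameters": {
      "additionalProperties": true,
      "title": "Parameters",
      "type": "object"
    },
    "schema": {
      "const": "phylotracks-domains-v1",
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
    "alignment",
    "architectures"
  ],
  "title": "DomainsDocument",
  "type": "object"
}
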