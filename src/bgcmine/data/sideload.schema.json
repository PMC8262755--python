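{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "bgcmine sideload annotation document",
  "description": "External-tool cluster annotations merged into detection output. All coordinates are 0-based half-open nucleotide positions.",
  "type": "object",
  "additionalProperties": false,
  "required": ["tool"],
  "properties": {
    "tool": {
      "type": "object",
      "additionalProperties": false,
      "required": ["name", "version"],
      "properties": {
        "name": {"type": "string", "minLength": 1},
        "version": {"type": "string", "minLength": 1},
        "description": {"type": "string"}
      }
    },
    "records": {
      "type": "array",
      "items": {
        "type": "object",
        "additionalProperties": false,
        "required": ["record_id"],
        "properties": {
          "record_id": {"type": "string", "minLength": 1},
          "subregions": {
            "type": "array",
            "items": {
              "type": "object",
              "additionalProperties": false,
              "required": ["start", "end", "label"],
              "properties": {
                "start": {"type": "integer", "minimum": 0},
                "end": {"type": "integer", "minimum": 1},
                "label": {"type": "string", "minLength": 1},
                "details": {"$ref": "#/$defs/details"}
              }
            }
          },
          "protoclusters": {
            "type": "array",
            "items": {
              "type": "object",
              "additionalProperties": false,
              "required": ["core_start", "core_end", "neighbourhood_start", "neighbourhood_end", "product"],
              "properties": {
                "core_start": {"type": "integer", "minimum": 0},
                "core_end": {"type": "integer", "minimum": 1},
                "neighbourhood_start": {"type": "integer", "minimum": 0},
                "neighbourhood_end": {"type": "integer", "minimum": 1},
                "product": {"type": "string", "minLength": 1},
                "details": {"$ref": "#/$defs/details"}
              }
            }
          }
        }
      }
    }
  },
  "$defs": {
    "details": {
      "type": "object",
      "additionalProperties": {
        "oneOf": [
          {"type": "string"},
          {"type": "array", "items": {"type": "string"}}
        ]
      }
    }
  }
}
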