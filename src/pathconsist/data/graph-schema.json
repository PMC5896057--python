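{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Generic concept-graph document",
  "description": "Interchange format for biological-process concept graphs: concepts (pathways, variants, components, functional units) plus typed parent->child relations. Validation is performed by pathconsist.sources.load_generic; this schema documents the contract.",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "concepts": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id"],
        "additionalProperties": false,
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "label": {"type": "string"},
          "category": {"enum": ["pathway", "variant", "component", "functional-unit", "other"]},
          "dispensable": {"type": "boolean"}
        }
      }
    },
    "relations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["parent", "child", "kind"],
        "additionalProperties": false,
        "properties": {
          "parent": {"type": "string"},
          "child": {"type": "string"},
          "kind": {"enum": ["part", "subtype"]}
        }
      }
    }
  }
}
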