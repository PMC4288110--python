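{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "$id": "https://example.org/nutridss/network.schema.json",
 "title": "NutriDSS discrete Bayesian network specification",
 "description": "One diagnostic subnet: nodes with ordered states, parents, and a conditional probability table stored as explicit rows. The document is validated in-process by pydantic models mirroring this schema.",
 "type": "object",
 "required": ["name", "version", "nodes"],
 "properties": {
  "name": {"type": "string", "minLength": 1},
  "version": {"type": "string"},
  "metadata": {
   "type": "object",
   "properties": {
    "provenance": {"type": "string"},
    "cpt_provenance": {"type": "string"},
    "description": {"type": "string"}
   },
   "additionalProperties": true
  },
  "nodes": {
   "type": "array",
   "minItems": 1,
   "items": {
    "type": "object",
    "required": ["name", "states", "cpt"],
    "properties": {
     "name": {"type": "string", "minLength": 1},
     "states": {
      "type": "array",
      "minItems": 2,
      "items": {"type": "string"},
      "uniqueItems": true
     },
     "parents": {"type": "array", "items": {"type": "string"}, "default": []},
     "cpt": {
      "type": "array",
      "minItems": 1,
      "items": {
       "type": "object",
       "required": ["given", "dist"],
       "properties": {
        "given": {
         "type": "object",
         "additionalProperties": {"type": "string"},
         "description": "parent name -> parent state; empty object for a root node"
        },
        "dist": {
         "type": "object",
         "additionalProperties": {"type": "number", "minimum": 0, "maximum": 1},
         "description": "state -> probability; must sum to 1 within 1e-9"
        }
       },
       "additionalProperties": false
      }
     }
    },
    "additionalProperties": false
   }
  }
 },
 "additionalProperties": false
}
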