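{
  "type": "object",
  "required": ["row_levels", "col_levels", "measures", "row_headers", "col_headers", "cells"],
  "properties": {
    "row_levels": {"type": "array", "items": {"type": "string"}},
    "col_levels": {"type": "array", "items": {"type": "string"}},
    "measures": {
      "type": "array",
      "items": {"enum": ["n", "mean", "median", "min", "max", "sd", "cv"]}
    },
    "row_headers": {"type": "array", "items": {"type": "array", "items": {"type": "string"}}},
    "col_headers": {"type": "array", "items": {"type": "array", "items": {"type": "string"}}},
    "cells": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["row", "col", "measures"],
        "properties": {
          "row": {"type": "array", "items": {"type": "string"}},
          "col": {"type": "array", "items": {"type": "string"}},
          "measures": {
            "type": "object",
            "properties": {
              "n": {"type": "integer"},
              "mean": {"type": ["number", "null"]},
              "median": {"type": ["number", "null"]},
              "min": {"type": ["number", "null"]},
              "max": {"type": ["number", "null"]},
              "sd": {"type": ["number", "null"]},
              "cv": {"type": ["number", "null"]}
            }
          }
        }
      }
    }
  }
}
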