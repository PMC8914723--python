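{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "nirfm pipeline configuration",
  "type": "object",
  "additionalProperties": false,
  "required": ["seed", "output_dir"],
  "properties": {
    "seed": {"type": "integer", "minimum": 0},
    "output_dir": {"type": "string"},
    "spectra": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "n_veg": {"type": "integer", "minimum": 4},
        "n_fm": {"type": "integer", "minimum": 4},
        "grid_points": {"type": "integer", "minimum": 16},
        "include_water_mimic": {"type": "boolean"}
      }
    },
    "preprocess": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "methods": {"type": "array", "items": {"type": "string"}},
        "window": {"type": "integer", "minimum": 3},
        "polyorder": {"type": "integer", "minimum": 1}
      }
    },
    "split": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "calibration_fraction": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1}
      }
    },
    "pls": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "max_lv": {"type": "integer", "minimum": 1},
        "folds": {"type": "integer", "minimum": 2},
        "autoscale": {"type": "boolean"}
      }
    },
    "selection": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "wrc": {"type": "object", "additionalProperties": false, "properties": {
          "k": {"type": "integer", "minimum": 1},
          "min_separation_nm": {"type": "number", "minimum": 0}
        }},
        "vip": {"type": "object", "additionalProperties": false, "properties": {
          "n_lv": {"type": "integer", "minimum": 1},
          "folds": {"type": "integer", "minimum": 2}
        }},
        "sfs": {"type": "object", "additionalProperties": false, "properties": {
          "max_features": {"type": "integer", "minimum": 1},
          "folds": {"type": "integer", "minimum": 2}
        }},
        "spa": {"type": "object", "additionalProperties": false, "properties": {
          "min_vars": {"type": "integer", "minimum": 2},
          "max_vars": {"type": "integer", "minimum": 2},
          "folds": {"type": "integer", "minimum": 2}
        }},
        "ipls": {"type": "object", "additionalProperties": false, "properties": {
          "interval_width": {"type": "integer", "minimum": 1},
          "max_lv": {"type": "integer", "minimum": 1},
          "max_intervals_selected": {"type": "integer", "minimum": 1},
          "folds": {"type": "integer", "minimum": 2}
        }}
      }
    },
    "imaging": {
      "type": "object",
      "additionalProperties": false,
      "properties": {
        "n_scenes": {"type": "integer", "minimum": 1},
        "lines": {"type": "integer", "minimum": 16},
        "pixels": {"type": "integer", "minimum": 16},
        "include_water_mimic": {"type": "boolean"},
        "noise_scale": {"type": "number", "minimum": 0},
        "min_blob": {"type": "integer", "minimum": 1},
        "median_filter": {"type": "boolean"},
        "combinations": {
          "type": "array",
          "items": {"type": "array", "items": {"type": "number"}}
        }
      }
    }
  }
}
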