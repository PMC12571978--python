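{
  "$defs": {
    "GeometryConfig": {
      "additionalProperties": false,
      "properties": {
        "wall_distance_cm": {
          "default": 192.0,
          "exclusiveMinimum": 0,
          "title": "Wall Distance Cm",
          "type": "number"
        },
        "horizontal_spacing_cm": {
          "default": 51.4,
          "exclusiveMinimum": 0,
          "title": "Horizontal Spacing Cm",
          "type": "number"
        },
        "vertical_spacing_cm": {
          "default": 51.4,
          "exclusiveMinimum": 0,
          "title": "Vertical Spacing Cm",
          "type": "number"
        }
      },
      "title": "GeometryConfig",
      "type": "object"
    },
    "PathsConfig": {
      "additionalProperties": false,
      "properties": {
        "trials_csv": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Trials Csv"
        },
        "metadata_csv": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Metadata Csv"
        },
        "output_dir": {
          "default": "rwpt_output",
          "title": "Output Dir",
          "type": "string"
        }
      },
      "title": "PathsConfig",
      "type": "object"
    },
    "ScoringConfig": {
      "additionalProperties": false,
      "properties": {
        "calibration_threshold_deg": {
          "default": 10.0,
          "exclusiveMinimum": 0,
          "title": "Calibration Threshold Deg",
          "type": "number"
        },
        "aggregate_map": {
          "additionalProperties": {
            "items": {
              "type": "string"
            },
            "type": "array"
          },
          "title": "Aggregate Map",
          "type": "object"
        }
      },
      "title": "ScoringConfig",
      "type": "object"
    },
    "SimulationBlock": {
      "additionalProperties": false,
      "properties": {
        "group_sizes": {
          "additionalProperties": {
            "type": "integer"
          },
          "title": "Group Sizes",
          "type": "object"
        },
        "repeats": {
          "default": 1,
          "minimum": 1,
          "title": "Repeats",
          "type": "integer"
        },
        "master_seed": {
          "default": 0,
          "title": "Master Seed",
          "type": "integer"
        },
        "parameters": {
          "additionalProperties": {
            "additionalProperties": {
              "type": "number"
            },
            "type": "object"
          },
          "title": "Parameters",
          "type": "object"
        }
      },
      "title": "SimulationBlock",
      "type": "object"
    },
    "StatisticsBlock": {
      "additionalProperties": false,
      "properties": {
        "alpha": {
          "default": 0.05,
          "exclusiveMaximum": 1,
          "exclusiveMinimum": 0,
          "title": "Alpha",
          "type": "number"
        },
        "levene_alpha": {
          "default": 0.05,
          "exclusiveMaximum": 1,
          "exclusiveMinimum": 0,
          "title": "Levene Alpha",
          "type": "number"
        },
        "posthoc": {
          "default": "bootstrap-tukey",
          "title": "Posthoc",
          "type": "string"
        },
        "n_boot": {
          "default": 1000,
          "minimum": 1,
          "title": "N Boot",
          "type": "integer"
        },
        "seed": {
          "default": 0,
          "title": "Seed",
          "type": "integer"
        }
      },
      "title": "StatisticsBlock",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "geometry": {
      "$ref": "#/$defs/GeometryConfig"
    },
    "scoring": {
      "$ref": "#/$defs/ScoringConfig"
    },
    "simulation": {
      "$ref": "#/$defs/SimulationBlock"
    },
    "statistics": {
      "$ref": "#/$defs/StatisticsBlock"
    },
    "paths": {
      "$ref": "#/$defs/PathsConfig"
    }
  },
  "title": "RunConfig",
  "type": "object"
}
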