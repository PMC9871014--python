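{
  "$defs": {
    "MetricSection": {
      "additionalProperties": false,
      "properties": {
        "bootstrap_ci": {
          "anyOf": [
            {
              "maxItems": 2,
              "minItems": 2,
              "prefixItems": [
                {
                  "type": "number"
                },
                {
                  "type": "number"
                }
              ],
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Bootstrap Ci"
        },
        "bootstrap_seed": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Bootstrap Seed"
        },
        "candidate_name": {
          "title": "Candidate Name",
          "type": "string"
        },
        "log_base": {
          "title": "Log Base",
          "type": "number"
        },
        "mean_candidate_term": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "string"
            }
          ],
          "title": "Mean Candidate Term"
        },
        "mean_delta": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "string"
            }
          ],
          "title": "Mean Delta"
        },
        "mean_reference_entropy": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "string"
            }
          ],
          "title": "Mean Reference Entropy"
        },
        "mode": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Mode"
        },
        "n_boot": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "N Boot"
        },
        "n_samples": {
          "title": "N Samples",
          "type": "integer"
        },
        "per_sample_delta": {
          "items": {
            "anyOf": [
              {
                "type": "number"
              },
              {
                "type": "string"
              }
            ]
          },
          "title": "Per Sample Delta",
          "type": "array"
        },
        "phase": {
          "title": "Phase",
          "type": "string"
        },
        "reference_name": {
          "title": "Reference Name",
          "type": "string"
        },
        "warnings": {
          "items": {
            "type": "string"
          },
          "title": "Warnings",
          "type": "array"
        }
      },
      "required": [
        "phase",
        "reference_name",
        "candidate_name",
        "n_samples",
        "log_base",
        "mean_delta",
        "mean_reference_entropy",
        "mean_candidate_term",
        "per_sample_delta"
      ],
      "title": "MetricSection",
      "type": "object"
    },
    "NetBenefitSection": {
      "additionalProperties": false,
      "properties": {
        "model_nb": {
          "items": {
            "type": "number"
          },
          "title": "Model Nb",
          "type": "array"
        },
        "n": {
          "title": "N",
          "type": "integer"
        },
        "prevalence": {
          "title": "Prevalence",
          "type": "number"
        },
        "thresholds": {
          "items": {
            "type": "number"
          },
          "title": "Thresholds",
          "type": "array"
        },
        "treat_all_nb": {
          "items": {
            "type": "number"
          },
          "title": "Treat All Nb",
          "type": "array"
        },
        "treat_none_nb": {
          "items": {
            "type": "number"
          },
          "title": "Treat None Nb",
          "type": "array"
        }
      },
      "required": [
        "thresholds",
        "model_nb",
        "treat_all_nb",
        "treat_none_nb",
        "n",
        "prevalence"
      ],
      "title": "NetBenefitSection",
      "type": "object"
    },
    "StrataSection": {
      "additionalProperties": false,
      "properties": {
        "correct_fraction": {
          "title": "Correct Fraction",
          "type": "number"
        },
        "n_ties": {
          "title": "N Ties",
          "type": "integer"
        },
        "rows": {
          "items": {
            "$ref": "#/$defs/StratumRow"
          },
          "title": "Rows",
          "type": "array"
        }
      },
      "required": [
        "rows",
        "n_ties",
        "correct_fraction"
      ],
      "title": "StrataSection",
      "type": "object"
    },
    "StratumRow": {
      "additionalProperties": false,
      "properties": {
        "mean_candidate_entropy": {
          "title": "Mean Candidate Entropy",
          "type": "number"
        },
        "mean_delta": {
          "title": "Mean Delta",
          "type": "number"
        },
        "n": {
          "title": "N",
          "type": "integer"
        },
        "stratum": {
          "title": "Stratum",
          "type": "string"
        }
      },
      "required": [
        "stratum",
        "n",
        "mean_delta",
        "mean_candidate_entropy"
      ],
      "title": "StratumRow",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "description": "Top-level actionability report.",
  "properties": {
    "action": {
      "anyOf": [
        {
          "$ref": "#/$defs/MetricSection"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "diagnosis": {
      "$ref": "#/$defs/MetricSection"
    },
    "net_benefit": {
      "anyOf": [
        {
          "$ref": "#/$defs/NetBenefitSection"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "schema_version": {
      "default": "1.0",
      "title": "Schema Version",
      "type": "string"
    },
    "strata": {
      "anyOf": [
        {
          "$ref": "#/$defs/StrataSection"
        },
        {
          "type": "null"
        }
      ],
      "default": null
    },
    "warnings": {
      "items": {
        "type": "string"
      },
      "title": "Warnings",
      "type": "array"
    }
  },
  "required": [
    "diagnosis"
  ],
  "title": "ReportDocument",
  "type": "object"
}
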