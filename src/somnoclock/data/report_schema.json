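{
  "$defs": {
    "AdjustedMeanBlock": {
      "additionalProperties": false,
      "properties": {
        "estimate": {
          "title": "Estimate",
          "type": "number"
        },
        "se": {
          "title": "Se",
          "type": "number"
        },
        "lower": {
          "title": "Lower",
          "type": "number"
        },
        "upper": {
          "title": "Upper",
          "type": "number"
        },
        "n": {
          "title": "N",
          "type": "integer"
        }
      },
      "required": [
        "estimate",
        "se",
        "lower",
        "upper",
        "n"
      ],
      "title": "AdjustedMeanBlock",
      "type": "object"
    },
    "AncovaBlock": {
      "additionalProperties": false,
      "properties": {
        "outcome": {
          "title": "Outcome",
          "type": "string"
        },
        "covariate": {
          "title": "Covariate",
          "type": "string"
        },
        "eval_at": {
          "title": "Eval At",
          "type": "number"
        },
        "slope": {
          "title": "Slope",
          "type": "number"
        },
        "slope_se": {
          "title": "Slope Se",
          "type": "number"
        },
        "fvalue": {
          "title": "Fvalue",
          "type": "number"
        },
        "df1": {
          "title": "Df1",
          "type": "integer"
        },
        "df2": {
          "title": "Df2",
          "type": "integer"
        },
        "pvalue": {
          "title": "Pvalue",
          "type": "number"
        },
        "mse": {
          "title": "Mse",
          "type": "number"
        },
        "adjusted_means": {
          "additionalProperties": {
            "$ref": "#/$defs/AdjustedMeanBlock"
          },
          "title": "Adjusted Means",
          "type": "object"
        },
        "contrasts": {
          "items": {
            "$ref": "#/$defs/ContrastBlock"
          },
          "title": "Contrasts",
          "type": "array"
        }
      },
      "required": [
        "outcome",
        "covariate",
        "eval_at",
        "slope",
        "slope_se",
        "fvalue",
        "df1",
        "df2",
        "pvalue",
        "mse",
        "adjusted_means",
        "contrasts"
      ],
      "title": "AncovaBlock",
      "type": "object"
    },
    "AnovaBlock": {
      "additionalProperties": false,
      "properties": {
        "fvalue": {
          "title": "Fvalue",
          "type": "number"
        },
        "df1": {
          "title": "Df1",
          "type": "integer"
        },
        "df2": {
          "title": "Df2",
          "type": "integer"
        },
        "pvalue": {
          "title": "Pvalue",
          "type": "number"
        },
        "group_means": {
          "additionalProperties": {
            "type": "number"
          },
          "title": "Group Means",
          "type": "object"
        }
      },
      "required": [
        "fvalue",
        "df1",
        "df2",
        "pvalue",
        "group_means"
      ],
      "title": "AnovaBlock",
      "type": "object"
    },
    "ContrastBlock": {
      "additionalProperties": false,
      "properties": {
        "groups": {
          "items": {
            "type": "string"
          },
          "title": "Groups",
          "type": "array"
        },
        "estimate": {
          "title": "Estimate",
          "type": "number"
        },
        "se": {
          "title": "Se",
          "type": "number"
        },
        "lower": {
          "title": "Lower",
          "type": "number"
        },
        "upper": {
          "title": "Upper",
          "type": "number"
        },
        "df": {
          "title": "Df",
          "type": "integer"
        }
      },
      "required": [
        "groups",
        "estimate",
        "se",
        "lower",
        "upper",
        "df"
      ],
      "title": "ContrastBlock",
      "type": "object"
    },
    "DescriptivesBlock": {
      "additionalProperties": false,
      "properties": {
        "n": {
          "title": "N",
          "type": "integer"
        },
        "mean": {
          "title": "Mean",
          "type": "number"
        },
        "sd": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Sd"
        },
        "min": {
          "title": "Min",
          "type": "number"
        },
        "max": {
          "title": "Max",
          "type": "number"
        },
        "median": {
          "title": "Median",
          "type": "number"
        }
      },
      "required": [
        "n",
        "mean",
        "min",
        "max",
        "median"
      ],
      "title": "DescriptivesBlock",
      "type": "object"
    },
    "ParticipantBlock": {
      "additionalProperties": false,
      "properties": {
        "participant_id": {
          "title": "Participant Id",
          "type": "string"
        },
        "tst": {
          "title": "Tst",
          "type": "number"
        },
        "sri": {
          "title": "Sri",
          "type": "number"
        },
        "duration_class": {
          "title": "Duration Class",
          "type": "string"
        },
        "regularity_class": {
          "title": "Regularity Class",
          "type": "string"
        },
        "group": {
          "title": "Group",
          "type": "string"
        },
        "age_diff_t1": {
          "title": "Age Diff T1",
          "type": "number"
        },
        "age_diff_t2": {
          "title": "Age Diff T2",
          "type": "number"
        },
        "age_diff_change": {
          "title": "Age Diff Change",
          "type": "number"
        }
      },
      "required": [
        "participant_id",
        "tst",
        "sri",
        "duration_class",
        "regularity_class",
        "group",
        "age_diff_t1",
        "age_diff_t2",
        "age_diff_change"
      ],
      "title": "ParticipantBlock",
      "type": "object"
    }
  },
  "additionalProperties": false,
  "properties": {
    "report_version": {
      "title": "Report Version",
      "type": "string"
    },
    "package_version": {
      "title": "Package Version",
      "type": "string"
    },
    "seed": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Seed"
    },
    "input_hashes": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Input Hashes",
      "type": "object"
    },
    "sri_median": {
      "title": "Sri Median",
      "type": "number"
    },
    "participants": {
      "items": {
        "$ref": "#/$defs/ParticipantBlock"
      },
      "title": "Participants",
      "type": "array"
    },
    "descriptives": {
      "additionalProperties": {
        "$ref": "#/$defs/DescriptivesBlock"
      },
      "title": "Descriptives",
      "type": "object"
    },
    "anova_t1": {
      "additionalProperties": {
        "$ref": "#/$defs/AnovaBlock"
      },
      "title": "Anova T1",
      "type": "object"
    },
    "ancova": {
      "additionalProperties": {
        "$ref": "#/$defs/AncovaBlock"
      },
      "title": "Ancova",
      "type": "object"
    }
  },
  "required": [
    "report_version",
    "package_version",
    "input_hashes",
    "sri_median",
    "participants",
    "descriptives",
    "anova_t1",
    "ancova"
  ],
  "title": "Report",
  "type": "object"
}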