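{
  "$defs": {
    "CategorizedNodule": {
      "description": "A nodule with its assigned category, management, and audit trace.",
      "properties": {
        "category": {
          "$ref": "#/$defs/NLCSPCategory"
        },
        "management": {
          "$ref": "#/$defs/ManagementRecommendation"
        },
        "nodule_id": {
          "title": "Nodule Id",
          "type": "string"
        },
        "pancan_risk": {
          "anyOf": [
            {
              "$ref": "#/$defs/PanCanRisk"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        },
        "rule_trace": {
          "items": {
            "type": "string"
          },
          "minItems": 1,
          "title": "Rule Trace",
          "type": "array"
        }
      },
      "required": [
        "nodule_id",
        "category",
        "management",
        "rule_trace"
      ],
      "title": "CategorizedNodule",
      "type": "object"
    },
    "FollowupDecision": {
      "description": "Category, management, growth numerics, and updated stability clock\nfor one tracked nodule at a follow-up scan.  A resolved nodule carries\nno category or management \u2014 it no longer contributes to the\nparticipant's result, but the resolution is recorded.",
      "properties": {
        "category": {
          "anyOf": [
            {
              "$ref": "#/$defs/NLCSPCategory"
            },
            {
              "type": "null"
            }
          ]
        },
        "growth": {
          "$ref": "#/$defs/GrowthStatus"
        },
        "management": {
          "anyOf": [
            {
              "$ref": "#/$defs/ManagementRecommendation"
            },
            {
              "type": "null"
            }
          ]
        },
        "nodule_id": {
          "title": "Nodule Id",
          "type": "string"
        },
        "rule_trace": {
          "items": {
            "type": "string"
          },
          "minItems": 1,
          "title": "Rule Trace",
          "type": "array"
        },
        "stability_clock_days": {
          "minimum": 0,
          "title": "Stability Clock Days",
          "type": "integer"
        }
      },
      "required": [
        "nodule_id",
        "growth",
        "category",
        "management",
        "stability_clock_days",
        "rule_trace"
      ],
      "title": "FollowupDecision",
      "type": "object"
    },
    "GrowthStatus": {
      "description": "A growth call plus the measured quantities behind it, for audit.",
      "properties": {
        "diameter_change_mm": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Diameter Change Mm"
        },
        "interval_days": {
          "minimum": 0,
          "title": "Interval Days",
          "type": "integer"
        },
        "method": {
          "anyOf": [
            {
              "$ref": "#/$defs/MeasurementMethod"
            },
            {
              "type": "null"
            }
          ],
          "default": null
        },
        "relative_volume_change_pct": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Relative Volume Change Pct"
        },
        "status": {
          "$ref": "#/$defs/GrowthStatusLabel"
        },
        "vdt_days": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Vdt Days"
        }
      },
      "required": [
        "status",
        "interval_days"
      ],
      "title": "GrowthStatus",
      "type": "object"
    },
    "GrowthStatusLabel": {
      "enum": [
        "growing",
        "slowly_growing",
        "stable",
        "decreased",
        "resolved",
        "new"
      ],
      "title": "GrowthStatusLabel",
      "type": "string"
    },
    "ManagementAction": {
      "enum": [
        "repeat_LDCT",
        "clinical_referral"
      ],
      "title": "ManagementAction",
      "type": "string"
    },
    "ManagementRecommendation": {
      "description": "What the participant should do next: repeat scan at an interval, or\nclinical referral (no interval).",
      "properties": {
        "action": {
          "$ref": "#/$defs/ManagementAction"
        },
        "descriptor": {
          "title": "Descriptor",
          "type": "string"
        },
        "interval_months": {
          "anyOf": [
            {
              "type": "integer"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Interval Months"
        }
      },
      "required": [
        "action",
        "descriptor"
      ],
      "title": "ManagementRecommendation",
      "type": "object"
    },
    "MeasurementMethod": {
      "enum": [
        "volumetry",
        "diameter"
      ],
      "title": "MeasurementMethod",
      "type": "string"
    },
    "NLCSPCategory": {
      "description": "The seven NLCSP categories.  1 < 2 < ... < 6 orders risk; 0 is the\northogonal \"incomplete\" category.",
      "enum": [
        0,
        1,
        2,
        3,
        4,
        5,
        6
      ],
      "title": "NLCSPCategory",
      "type": "integer"
    },
    "PanCanRisk": {
      "description": "A computed probability of lung cancer within the stated horizon.",
      "properties": {
        "horizon": {
          "$ref": "#/$defs/RiskHorizon",
          "default": "2y"
        },
        "probability": {
          "maximum": 1.0,
          "minimum": 0.0,
          "title": "Probability",
          "type": "number"
        }
      },
      "required": [
        "probability"
      ],
      "title": "PanCanRisk",
      "type": "object"
    },
    "RiskHorizon": {
      "enum": [
        "2y",
        "4y"
      ],
      "title": "RiskHorizon",
      "type": "string"
    }
  },
  "description": "One participant's result for one screening episode.",
  "properties": {
    "exam_complete": {
      "title": "Exam Complete",
      "type": "boolean"
    },
    "nodule_results": {
      "items": {
        "anyOf": [
          {
            "$ref": "#/$defs/CategorizedNodule"
          },
          {
            "$ref": "#/$defs/FollowupDecision"
          }
        ]
      },
      "title": "Nodule Results",
      "type": "array"
    },
    "overall_category": {
      "$ref": "#/$defs/NLCSPCategory"
    },
    "overall_management": {
      "$ref": "#/$defs/ManagementRecommendation"
    },
    "participant_id": {
      "title": "Participant Id",
      "type": "string"
    },
    "scan_date": {
      "format": "date",
      "title": "Scan Date",
      "type": "string"
    },
    "summary_text": {
      "title": "Summary Text",
      "type": "string"
    }
  },
  "required": [
    "participant_id",
    "scan_date",
    "exam_complete",
    "nodule_results",
    "overall_category",
    "overall_management",
    "summary_text"
  ],
  "title": "ScreeningEpisodeReport",
  "type": "object"
}
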