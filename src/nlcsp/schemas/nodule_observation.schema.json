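{
  "$defs": {
    "AirwayLevel": {
      "enum": [
        "none",
        "subsegmental",
        "segmental_or_proximal"
      ],
      "title": "AirwayLevel",
      "type": "string"
    },
    "Calcification": {
      "enum": [
        "none",
        "complete",
        "central",
        "popcorn",
        "concentric_ring",
        "other"
      ],
      "title": "Calcification",
      "type": "string"
    },
    "Composition": {
      "enum": [
        "solid",
        "part_solid",
        "ground_glass"
      ],
      "title": "Composition",
      "type": "string"
    },
    "CystFeatures": {
      "enum": [
        "none",
        "thick_walled",
        "multilocular"
      ],
      "title": "CystFeatures",
      "type": "string"
    },
    "Lobe": {
      "enum": [
        "RUL",
        "RML",
        "RLL",
        "LUL",
        "lingula",
        "LLL"
      ],
      "title": "Lobe",
      "type": "string"
    },
    "Margin": {
      "enum": [
        "smooth",
        "lobulated",
        "spiculated",
        "irregular"
      ],
      "title": "Margin",
      "type": "string"
    },
    "Shape": {
      "enum": [
        "oval",
        "lentiform",
        "triangular",
        "round",
        "irregular"
      ],
      "title": "Shape",
      "type": "string"
    }
  },
  "description": "One nodule's features as seen on one scan \u2014 the atomic input record.\n\n``nodule_id`` is a stable identifier linking observations of the same\nnodule across scans; matching is never computed by the engine.\n``volume_mm3`` absent means volumetry was not possible and diameter\nrules apply for growth assessment.",
  "properties": {
    "airway_level": {
      "$ref": "#/$defs/AirwayLevel",
      "default": "none"
    },
    "calcification": {
      "$ref": "#/$defs/Calcification",
      "default": "none"
    },
    "composition": {
      "$ref": "#/$defs/Composition"
    },
    "contacts_pleura": {
      "default": false,
      "title": "Contacts Pleura",
      "type": "boolean"
    },
    "cyst_features": {
      "$ref": "#/$defs/CystFeatures",
      "default": "none"
    },
    "distance_to_pleura_mm": {
      "anyOf": [
        {
          "minimum": 0,
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Distance To Pleura Mm"
    },
    "lobe": {
      "$ref": "#/$defs/Lobe"
    },
    "long_axis_mm": {
      "exclusiveMinimum": 0,
      "title": "Long Axis Mm",
      "type": "number"
    },
    "macroscopic_fat": {
      "default": false,
      "title": "Macroscopic Fat",
      "type": "boolean"
    },
    "margin": {
      "$ref": "#/$defs/Margin",
      "default": "smooth"
    },
    "nodule_count_total": {
      "default": 1,
      "minimum": 1,
      "title": "Nodule Count Total",
      "type": "integer"
    },
    "nodule_id": {
      "title": "Nodule Id",
      "type": "string"
    },
    "radiologist_suspicious_flag": {
      "default": false,
      "title": "Radiologist Suspicious Flag",
      "type": "boolean"
    },
    "scan_date": {
      "format": "date",
      "title": "Scan Date",
      "type": "string"
    },
    "shape": {
      "$ref": "#/$defs/Shape",
      "default": "round"
    },
    "short_axis_mm": {
      "exclusiveMinimum": 0,
      "title": "Short Axis Mm",
      "type": "number"
    },
    "solid_component_mean_diameter_mm": {
      "anyOf": [
        {
          "exclusiveMinimum": 0,
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Solid Component Mean Diameter Mm"
    },
    "spiculation": {
      "default": false,
      "title": "Spiculation",
      "type": "boolean"
    },
    "suspected_infection": {
      "default": false,
      "title": "Suspected Infection",
      "type": "boolean"
    },
    "upper_lobe": {
      "anyOf": [
        {
          "type": "boolean"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Upper Lobe"
    },
    "volume_mm3": {
      "anyOf": [
        {
          "exclusiveMinimum": 0,
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Volume Mm3"
    }
  },
  "required": [
    "nodule_id",
    "scan_date",
    "composition",
    "long_axis_mm",
    "short_axis_mm",
    "lobe"
  ],
  "title": "NoduleObservation",
  "type": "object"
}
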