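{
  "$defs": {
    "Sex": {
      "enum": [
        "female",
        "male"
      ],
      "title": "Sex",
      "type": "string"
    }
  },
  "description": "Participant-level risk-model inputs.\n\nAll four fields are required; the engine does not police age against a\nscreening-eligibility window \u2014 it classifies whatever it is given.",
  "properties": {
    "age": {
      "minimum": 0,
      "title": "Age",
      "type": "integer"
    },
    "emphysema": {
      "title": "Emphysema",
      "type": "boolean"
    },
    "family_history_lung_cancer": {
      "title": "Family History Lung Cancer",
      "type": "boolean"
    },
    "sex": {
      "$ref": "#/$defs/Sex"
    }
  },
  "required": [
    "age",
    "sex",
    "family_history_lung_cancer",
    "emphysema"
  ],
  "title": "ParticipantCovariates",
  "type": "object"
}
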