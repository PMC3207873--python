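{
  "$defs": {
    "CurrentMedication": {
      "description": "Antithrombotic the patient is taking at the time of the encounter.",
      "enum": [
        "none",
        "aspirin",
        "warfarin"
      ],
      "title": "CurrentMedication",
      "type": "string"
    }
  },
  "additionalProperties": false,
  "description": "Validated patient data-entry record.\n\nAll fields are required; a record with a missing flag is rejected rather\nthan defaulted, so that an unticked box can never be confused with an\nunasked question.",
  "properties": {
    "age": {
      "description": "Age in whole years",
      "maximum": 120,
      "minimum": 18,
      "title": "Age",
      "type": "integer"
    },
    "chf": {
      "description": "Congestive heart failure",
      "title": "Chf",
      "type": "boolean"
    },
    "hypertension": {
      "description": "History of hypertension",
      "title": "Hypertension",
      "type": "boolean"
    },
    "diabetes": {
      "title": "Diabetes",
      "type": "boolean"
    },
    "prior_stroke_tia": {
      "description": "Prior stroke or TIA",
      "title": "Prior Stroke Tia",
      "type": "boolean"
    },
    "hepatic_or_renal_disease": {
      "title": "Hepatic Or Renal Disease",
      "type": "boolean"
    },
    "ethanol_abuse": {
      "title": "Ethanol Abuse",
      "type": "boolean"
    },
    "malignancy": {
      "title": "Malignancy",
      "type": "boolean"
    },
    "reduced_platelets": {
      "description": "Reduced platelet count or function",
      "title": "Reduced Platelets",
      "type": "boolean"
    },
    "prior_major_bleed": {
      "description": "Prior major bleed (rebleeding risk)",
      "title": "Prior Major Bleed",
      "type": "boolean"
    },
    "uncontrolled_hypertension": {
      "title": "Uncontrolled Hypertension",
      "type": "boolean"
    },
    "anemia": {
      "title": "Anemia",
      "type": "boolean"
    },
    "genetic_factors": {
      "title": "Genetic Factors",
      "type": "boolean"
    },
    "fall_risk": {
      "description": "Excessive fall risk",
      "title": "Fall Risk",
      "type": "boolean"
    },
    "cad": {
      "description": "Coronary artery disease",
      "title": "Cad",
      "type": "boolean"
    },
    "current_medication": {
      "$ref": "#/$defs/CurrentMedication"
    }
  },
  "required": [
    "age",
    "chf",
    "hypertension",
    "diabetes",
    "prior_stroke_tia",
    "hepatic_or_renal_disease",
    "ethanol_abuse",
    "malignancy",
    "reduced_platelets",
    "prior_major_bleed",
    "uncontrolled_hypertension",
    "anemia",
    "genetic_factors",
    "fall_risk",
    "cad",
    "current_medication"
  ],
  "title": "PatientProfile",
  "type": "object"
}
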