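{
 "$defs": {
  "AdjustmentFlags": {
   "description": "Ternary flags feeding score upgrades and downgrades.\n\n``unknown`` never triggers a downgrade and never earns an upgrade.\n``early_stopping_or_crossover`` carries the Form 2b downgrade penalty.",
   "properties": {
    "toxicity_ge30pct_grade34": {
     "$ref": "#/$defs/Ternary",
     "default": "unknown"
    },
    "toxicity_reduced_vs_control": {
     "$ref": "#/$defs/Ternary",
     "default": "unknown"
    },
    "qol_assessed": {
     "$ref": "#/$defs/Ternary",
     "default": "unknown"
    },
    "qol_improved": {
     "$ref": "#/$defs/Ternary",
     "default": "unknown"
    },
    "phase4_confirmation": {
     "$ref": "#/$defs/Ternary",
     "default": "unknown"
    },
    "early_stopping_or_crossover": {
     "$ref": "#/$defs/Ternary",
     "default": "unknown"
    }
   },
   "title": "AdjustmentFlags",
   "type": "object"
  },
  "BestResponse": {
   "enum": [
    "CR",
    "PR",
    "MR",
    "SD",
    "PD"
   ],
   "title": "BestResponse",
   "type": "string"
  },
  "Design": {
   "enum": [
    "comparative_superiority",
    "comparative_noninferiority",
    "single_arm",
    "patient_n_of_1"
   ],
   "title": "Design",
   "type": "string"
  },
  "Endpoint": {
   "enum": [
    "OS",
    "PFS",
    "ORR",
    "other",
    "safety"
   ],
   "title": "Endpoint",
   "type": "string"
  },
  "HazardRatioEstimate": {
   "description": "Hazard-ratio point estimate with its 95% confidence limits.\n\nThe lower limit is the quantity ESMO-MCBS grading compares to its\nthresholds; ASCO-NHB uses the point estimate.",
   "properties": {
    "point": {
     "title": "Point",
     "type": "number"
    },
    "lower95": {
     "title": "Lower95",
     "type": "number"
    },
    "upper95": {
     "title": "Upper95",
     "type": "number"
    }
   },
   "required": [
    "point",
    "lower95",
    "upper95"
   ],
   "title": "HazardRatioEstimate",
   "type": "object"
  },
  "ResponseSummary": {
   "description": "Response-based outcomes of a single-arm study or patient.\n\nORR counts CR+PR+MR; DCR additionally counts SD.  DoR/DoCB are the\ndurations over which response / disease control was maintained.",
   "properties": {
    "orr_pct": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Orr Pct"
    },
    "dcr_pct": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Dcr Pct"
    },
    "dor_months": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Dor Months"
    },
    "dor_statistic": {
     "default": "unspecified",
     "title": "Dor Statistic",
     "type": "string"
    },
    "docb_months": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Docb Months"
    },
    "response_criteria": {
     "anyOf": [
      {
       "type": "string"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Response Criteria"
    }
   },
   "title": "ResponseSummary",
   "type": "object"
  },
  "SurvivalEndpoint": {
   "description": "One survival endpoint (OS or PFS) of a comparative trial.",
   "properties": {
    "endpoint_kind": {
     "$ref": "#/$defs/Endpoint"
    },
    "gain_months": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Gain Months"
    },
    "control_median_months": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Control Median Months"
    },
    "hr": {
     "anyOf": [
      {
       "$ref": "#/$defs/HazardRatioEstimate"
      },
      {
       "type": "null"
      }
     ],
     "default": null
    },
    "landmark_gain_pct": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Landmark Gain Pct"
    },
    "landmark_years": {
     "anyOf": [
      {
       "type": "integer"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "Landmark Years"
    }
   },
   "required": [
    "endpoint_kind"
   ],
   "title": "SurvivalEndpoint",
   "type": "object"
  },
  "Ternary": {
   "enum": [
    "yes",
    "no",
    "unknown"
   ],
   "title": "Ternary",
   "type": "string"
  }
 },
 "description": "One scorable study-outcome record (a trial, a trial arm/cohort, or an n-of-1 patient). Generated from the package's pydantic model; a JSON records file is an array of these objects.",
 "properties": {
  "record_id": {
   "title": "Record Id",
   "type": "string"
  },
  "design": {
   "$ref": "#/$defs/Design"
  },
  "primary_endpoint": {
   "$ref": "#/$defs/Endpoint"
  },
  "n_subjects": {
   "anyOf": [
    {
     "type": "integer"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "N Subjects"
  },
  "superiority_met": {
   "$ref": "#/$defs/Ternary",
   "default": "unknown"
  },
  "noninferiority_met": {
   "$ref": "#/$defs/Ternary",
   "default": "unknown"
  },
  "os": {
   "anyOf": [
    {
     "$ref": "#/$defs/SurvivalEndpoint"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "pfs": {
   "anyOf": [
    {
     "$ref": "#/$defs/SurvivalEndpoint"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "single_arm_pfs_months": {
   "anyOf": [
    {
     "type": "number"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Single Arm Pfs Months"
  },
  "response": {
   "anyOf": [
    {
     "$ref": "#/$defs/ResponseSummary"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "best_response": {
   "anyOf": [
    {
     "$ref": "#/$defs/BestResponse"
    },
    {
     "type": "null"
    }
   ],
   "default": null
  },
  "flags": {
   "$ref": "#/$defs/AdjustmentFlags",
   "default": {
    "toxicity_ge30pct_grade34": "unknown",
    "toxicity_reduced_vs_control": "unknown",
    "qol_assessed": "unknown",
    "qol_improved": "unknown",
    "phase4_confirmation": "unknown",
    "early_stopping_or_crossover": "unknown"
   }
  },
  "subgroup_label": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Subgroup Label"
  },
  "entity": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Entity"
  },
  "therapy_class": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Therapy Class"
  },
  "note": {
   "anyOf": [
    {
     "type": "string"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Note"
  }
 },
 "required": [
  "record_id",
  "design",
  "primary_endpoint"
 ],
 "title": "StudyRecord",
 "type": "object",
 "$schema": "https://json-schema.org/draft/2020-12/schema"
}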