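[
  {"outcome_id": "ugags", "label": "Urinary GAGs", "direction": "benefit", "soe_grade": "moderate"},
  {"outcome_id": "liver", "label": "Liver volume", "direction": "benefit", "soe_grade": "moderate"},
  {"outcome_id": "antibodies", "label": "Antibody development", "direction": "harm", "soe_grade": "moderate", "harm_criterion": "documented"},
  {"outcome_id": "6mwt", "label": "6-min walk test", "direction": "benefit", "soe_grade": "low"},
  {"outcome_id": "jrom", "label": "Joint range of motion", "direction": "benefit", "soe_grade": "insufficient"},
  {"outcome_id": "growth", "label": "Growth (height)", "direction": "benefit", "soe_grade": "low"},
  {"outcome_id": "irr", "label": "Infusion-related reactions", "direction": "harm", "soe_grade": "low", "harm_criterion": "dose_change"},
  {"outcome_id": "pulmonary", "label": "Pulmonary function (FVC%)", "direction": "benefit", "soe_grade": "low"},
  {"outcome_id": "cardiac", "label": "Cardiac function", "direction": "benefit", "soe_grade": "insufficient"},
  {"outcome_id": "qol", "label": "Quality of life", "direction": "benefit", "soe_grade": "insufficient"},
  {"outcome_id": "sleep", "label": "Sleep apnea", "direction": "benefit", "soe_grade": "insufficient"}
]
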