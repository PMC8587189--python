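{
  "schema_version": "1",
  "_comment": "SYNTHETIC example registry document. Cohort fractions, baseline outcomes and hazard ratios are illustrative values for demonstrating the pipeline; the actual published hazard ratios must be supplied by the user from the cited registry studies.",
  "cohort": {
    "donor_type": "matched_sibling",
    "source_label": "synthetic illustrative cohort (not published registry values)",
    "follow_up_months": 36,
    "n_total": 736,
    "age_bins": [
      {"lower": 0, "upper": 5, "count": 175, "printed_percent": 23.8,
       "outcome_probabilities": {"OS": 0.96, "EFS": 0.93, "graft_failure": 0.03,
                                  "acute_GVHD": 0.12, "chronic_GVHD": 0.09}},
      {"lower": 6, "upper": 15, "count": 436, "printed_percent": 59.2,
       "outcome_probabilities": {"OS": 0.93, "EFS": 0.90, "graft_failure": 0.04,
                                  "acute_GVHD": 0.15, "chronic_GVHD": 0.12}},
      {"lower": 15, "upper": null, "cap": 25, "count": 125, "printed_percent": 17,
       "outcome_probabilities": {"OS": 0.88, "EFS": 0.84, "graft_failure": 0.06,
                                  "acute_GVHD": 0.20, "chronic_GVHD": 0.17}}
    ],
    "level_fractions": {
      "sex": {"F": 0.48, "M": 0.52},
      "stem_cell_source": {"bone_marrow": 0.74, "cord_blood": 0.26},
      "conditioning": {"myeloablative": 0.85, "reduced_intensity": 0.15}
    },
    "baseline_outcomes": {
      "OS": 0.93, "EFS": 0.90, "graft_failure": 0.04,
      "acute_GVHD": 0.15, "chronic_GVHD": 0.12
    }
  },
  "hazard_ratios": [
    {"outcome": "OS", "donor_type": "matched_sibling",
     "entries": {"sex": {"F": 1.0, "M": 1.2},
                 "stem_cell_source": {"bone_marrow": 1.0, "cord_blood": 1.3},
                 "conditioning": {"myeloablative": 1.0, "reduced_intensity": 1.4}},
     "reference_levels": {"sex": "F", "stem_cell_source": "bone_marrow",
                           "conditioning": "myeloablative"}},
    {"outcome": "EFS", "donor_type": "matched_sibling",
     "entries": {"sex": {"F": 1.0, "M": 1.2},
                 "stem_cell_source": {"bone_marrow": 1.0, "cord_blood": 1.4},
                 "conditioning": {"myeloablative": 1.0, "reduced_intensity": 1.5}},
     "reference_levels": {"sex": "F", "stem_cell_source": "bone_marrow",
                           "conditioning": "myeloablative"}},
    {"outcome": "graft_failure", "donor_type": "matched_sibling",
     "entries": {"sex": {"F": 1.0, "M": 1.1},
                 "stem_cell_source": {"bone_marrow": 1.0, "cord_blood": 1.8},
                 "conditioning": {"myeloablative": 1.0, "reduced_intensity": 2.0}},
     "reference_levels": {"sex": "F", "stem_cell_source": "bone_marrow",
                           "conditioning": "myeloablative"}},
    {"outcome": "acute_GVHD", "donor_type": "matched_sibling",
     "entries": {"sex": {"F": 1.0, "M": 1.15},
                 "stem_cell_source": {"bone_marrow": 1.0, "cord_blood": 0.7},
                 "conditioning": {"myeloablative": 1.0, "reduced_intensity": 0.9}},
     "reference_levels": {"sex": "F", "stem_cell_source": "bone_marrow",
                           "conditioning": "myeloablative"}},
    {"outcome": "chronic_GVHD", "donor_type": "matched_sibling",
     "entries": {"sex": {"F": 1.0, "M": 1.1},
                 "stem_cell_source": {"bone_marrow": 1.0, "cord_blood": 0.6},
                 "conditioning": {"myeloablative": 1.0, "reduced_intensity": 0.85}},
     "reference_levels": {"sex": "F", "stem_cell_source": "bone_marrow",
                           "conditioning": "myeloablative"}}
  ]
}
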