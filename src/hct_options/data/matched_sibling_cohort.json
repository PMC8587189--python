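{
  "schema_version": "1",
  "cohort": {
    "donor_type": "matched_sibling",
    "source_label": "HLA antigen-matched sibling registry cohort, published age-bin counts; follow-up horizon illustrative",
    "follow_up_months": 36,
    "n_total": 736,
    "age_bins": [
      {"lower": 0, "upper": 5, "count": 175, "printed_percent": 23.8},
      {"lower": 6, "upper": 15, "count": 436, "printed_percent": 59.2},
      {"lower": 15, "upper": null, "cap": 25, "count": 125, "printed_percent": 17}
    ],
    "level_fractions": {},
    "baseline_outcomes": {}
  }
}
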