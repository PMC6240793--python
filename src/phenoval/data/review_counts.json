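{
  "description": "Printed chart-review tallies of the aspirin-dosing trial eligibility validation study (300 records requested; two-expert review with conference consensus).",
  "requested": 300,
  "obtained": 185,
  "abstractor_confirmed": 158,
  "abstractor_non_confirmed": 27,
  "expert_reviewed_confirmed_sample": 10,
  "dual_reversals_to_confirmed": 6,
  "dual_cad_only_reversals": 2,
  "dual_verified_non_confirmed": 12,
  "split_cases": {
    "total": 7,
    "stand": 1,
    "reverse_to_confirmed": 4,
    "cad_only": 2
  },
  "nonconfirm_categories": {
    "exclusion_present": 5,
    "cad_only": 4,
    "no_evidence": 8
  },
  "exclusion_detail": {
    "aspirin_allergy": 2,
    "gi_bleed": 3
  },
  "strata": {
    "ami": {"n": 107, "confirmed": 97},
    "pci_cabg": {"n": 78, "confirmed": 71}
  },
  "sex": {
    "male": {"n": 115, "confirmed": 106},
    "female": {"n": 70, "confirmed": 62}
  },
  "age": {
    "ge_65": {"n": 150, "confirmed": 134},
    "lt_65": {"n": 35, "confirmed": 34}
  }
}
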