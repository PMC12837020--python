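{
  "description": "Published 2024 KSA base-case results: component totals (SAR) of the national cost-of-illness analysis, and the SAR / international-dollar unit-cost pairs from which the purchasing-power-parity rate is derived. Used for aggregation-identity checks and reporting layout only, never as engine inputs.",
  "direct_components_sar": {
    "medication": 70610172590,
    "surgery_resources": 11319029616,
    "adverse_events": 2323124452,
    "psychological": 1535131658,
    "visual_aids": 1619612282,
    "home_nurse": 13719775687
  },
  "indirect_components_sar": {
    "pension": 17798627918,
    "patient_productivity": 30314412406,
    "caregiver_productivity": 1085025576
  },
  "totals_sar": {
    "direct": 101126846285,
    "indirect": 49198065900,
    "grand": 150324912186
  },
  "per_patient_sar": {
    "R1": {"direct": 300046, "indirect": 145972},
    "R2": {"direct": 1326203, "indirect": 645196},
    "R3": {"direct": 1700260, "indirect": 827174},
    "R4": {"direct": 1894575, "indirect": 921708},
    "M1": {"direct": 98685, "indirect": 13568},
    "M2": {"direct": 139225, "indirect": 162180}
  },
  "unit_cost_pairs_sar_intl": [
    [2942.40, 1590.49],
    [1.26, 0.68],
    [26.60, 14.38],
    [6.40, 3.46],
    [45.15, 24.41],
    [76.90, 41.57],
    [51.55, 27.86],
    [95.40, 51.57],
    [295.05, 159.49],
    [2000.00, 1081.08],
    [1200.00, 648.65],
    [380.00, 205.41],
    [345.00, 186.49],
    [60.00, 32.43],
    [180.00, 97.30],
    [480.00, 259.46],
    [180.00, 97.30],
    [3200.00, 1729.73],
    [1600.00, 864.86],
    [600.00, 324.32],
    [3400.00, 1837.84],
    [80.00, 43.24],
    [40.00, 21.62],
    [3000.00, 1621.62],
    [4400.00, 2378.38],
    [2800.00, 1513.51],
    [520.00, 281.08],
    [520.00, 281.08],
    [104.00, 56.22],
    [104.00, 56.22],
    [160.00, 86.49],
    [1500.00, 810.81],
    [104.00, 56.22],
    [345.00, 186.49],
    [37000.00, 20000.00],
    [4000.00, 2162.16]
  ]
}
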