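{
  "description": "Published reference counts from the source study's pooled NSCLC cohort (162 anti-PD1/PDL1-treated patients) used to verify the statistics engine.",
  "pooled_2x2": {
    "comment": "rows: ICR2-4 then ICR1; columns: DCB yes, DCB no",
    "table": [[44, 83], [3, 32]],
    "expected": {"odds_ratio": 5.65, "ci_low": 1.64, "ci_high": 19.51}
  },
  "own_cohort_2x2": {
    "comment": "authors' own 44-patient cohort; rows: ICR2-4 then ICR1",
    "table": [[10, 25], [1, 8]],
    "expected": {"odds_ratio": 3.20, "ci_low": 0.35, "ci_high": 29.01}
  },
  "overall_dcb": {"events": 47, "n": 162, "expected_percent": 29},
  "class_sizes": {"ICR1": 35, "ICR2": 48, "ICR3": 36, "ICR4": 43},
  "class_dcb_events": {"ICR1": 3, "ICR2": 17, "ICR3": 13, "ICR4": 14},
  "rates": {
    "icr1_percent": {"events": 3, "n": 35, "expected_percent": 9},
    "icr24_percent": {"events": 44, "n": 127, "expected_percent": 35}
  }
}
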