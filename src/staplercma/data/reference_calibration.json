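{
  "comment": "Aggregate-calibrated decision-model inputs (CNY per episode). 'manual_baseline' holds the published ECHELON-manual base-case costs for the five regression-driven categories; the powered scenario multiplies each by exp(stapler coefficient). 'victor_acquisition' holds the published Victor Medical acquisition cells, which the published analysis reports directly (they are not equal to utilization x Victor unit prices; both routes are exposed in the engine).",
  "manual_baseline": {
    "disposables": 9989.0,
    "drugs": 13043.0,
    "operation": 7643.0,
    "laboratory": 11162.0,
    "other": 2248.0
  },
  "victor_acquisition": {
    "stapler": 4882.0,
    "cartridge": 20974.0
  }
}
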