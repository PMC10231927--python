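{
  "_comment": "SYNTHETIC seven-budget worm-style ensemble. This is a plausible reconstruction built from densities in {0.1, 0.3, 1, 3} OD with the published triplet structure (a,b,d and c,e,f hold the M price constant; d,e,g hold the H price constant; e offers both foods at OD 1). It is NOT a recorded ensemble; use it for demonstrations and power analyses only.",
  "budgets": [
    {"budget_id": "a", "d_H": 0.1, "d_M": 3.0},
    {"budget_id": "b", "d_H": 0.3, "d_M": 3.0},
    {"budget_id": "c", "d_H": 0.3, "d_M": 1.0},
    {"budget_id": "d", "d_H": 1.0, "d_M": 3.0},
    {"budget_id": "e", "d_H": 1.0, "d_M": 1.0},
    {"budget_id": "f", "d_H": 3.0, "d_M": 1.0},
    {"budget_id": "g", "d_H": 1.0, "d_M": 0.3}
  ]
}
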