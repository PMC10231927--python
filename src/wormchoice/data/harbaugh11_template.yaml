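# Template for the 11-budget human-style ensemble used as a stringent GARP
# power benchmark.  The budget definitions are published externally and are
# not redistributed here: replace every null with the published price/income
# values (or intercepts d_H/d_M) before use.  Loading this file unmodified
# raises a validation error.
budgets:
  - {budget_id: "1", p_x: null, p_y: null, income: null}
  - {budget_id: "2", p_x: null, p_y: null, income: null}
  - {budget_id: "3", p_x: null, p_y: null, income: null}
  - {budget_id: "4", p_x: null, p_y: null, income: null}
  - {budget_id: "5", p_x: null, p_y: null, income: null}
  - {budget_id: "6", p_x: null, p_y: null, income: null}
  - {budget_id: "7", p_x: null, p_y: null, income: null}
  - {budget_id: "8", p_x: null, p_y: null, income: null}
  - {budget_id: "9", p_x: null, p_y: null, income: null}
  - {budget_id: "10", p_x: null, p_y: null, income: null}
  - {budget_id: "11", p_x: null, p_y: null, income: null}
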