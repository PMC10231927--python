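{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "wormchoice analysis report",
  "type": "object",
  "required": ["provenance", "groups"],
  "properties": {
    "provenance": {
      "type": "object",
      "required": ["version", "config_digest", "seed", "n_sims"],
      "properties": {
        "version": {"type": "string"},
        "config_digest": {"type": "string"},
        "seed": {"type": "integer"},
        "n_sims": {"type": "integer"},
        "choices_path": {"type": "string"}
      }
    },
    "groups": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["summary", "garp", "sigmoid", "ces_tobit", "simulations"],
        "properties": {
          "summary": {"type": "array", "items": {"type": "object"}},
          "garp": {
            "type": "object",
            "required": ["passes", "n_direct", "n_indirect", "ccei", "violations"],
            "properties": {
              "passes": {"type": "boolean"},
              "n_direct": {"type": "integer"},
              "n_indirect": {"type": "integer"},
              "ccei": {"type": "number"},
              "violations": {"type": "array", "items": {"type": "object"}}
            }
          },
          "sigmoid": {
            "type": "object",
            "required": ["r0", "k", "rss"],
            "properties": {
              "r0": {"type": "number"},
              "k": {"type": "number"},
              "rss": {"type": "number"}
            }
          },
          "ces_tobit": {
            "type": "object",
            "required": ["beta", "rho", "sigma", "loglik", "n_obs", "converged"],
            "properties": {
              "beta": {"type": "number"},
              "rho": {"type": "number"},
              "sigma": {"type": "number"},
              "loglik": {"type": "number"},
              "n_obs": {"type": "integer"},
              "converged": {"type": "boolean"}
            }
          },
          "simulations": {
            "type": "object",
            "additionalProperties": {
              "type": "object",
              "required": ["probability", "n_sims", "ci95"],
              "properties": {
                "probability": {"type": "number"},
                "n_sims": {"type": "integer"},
                "ci95": {"type": "array", "items": {"type": "number"}}
              }
            }
          }
        }
      }
    }
  }
}
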