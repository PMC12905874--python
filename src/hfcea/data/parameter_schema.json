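{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "hfcea parameter configuration",
  "description": "Model inputs for the one-year heart-failure adherence decision tree: one record per parameter (base value, uncertainty range, range basis, sampling-distribution family, units) plus model constants. The package validates configurations against these rules in code; this document is the normative description of the format.",
  "type": "object",
  "required": ["parameters", "constants"],
  "properties": {
    "parameters": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "base", "low", "high", "basis", "family", "units"],
        "properties": {
          "name": {"type": "string", "pattern": "^[a-z][a-z0-9_]*$"},
          "base": {"type": "number"},
          "low": {"type": "number"},
          "high": {"type": "number"},
          "basis": {"enum": ["ci95", "pct25", "pct50", "literature_range"]},
          "family": {"enum": ["beta", "gamma", "fixed"]},
          "units": {"enum": ["probability", "utility", "usd"]}
        },
        "additionalProperties": false
      }
    },
    "constants": {
      "type": "object",
      "required": [
        "wtp_threshold",
        "n_psa_iterations",
        "death_month",
        "exac_duration_months",
        "hazard_ratio_nonadherent",
        "cohort_age"
      ],
      "additionalProperties": {"type": "number"}
    }
  },
  "additionalProperties": false,
  "$comment": "Semantic constraints enforced in code: low <= base <= high; family=beta implies 0 <= low and high <= 1; family=gamma implies low > 0; all 18 canonical parameter names present exactly once."
}
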