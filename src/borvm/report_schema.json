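{
  "$comment": "Shape of the experiment report emitted by borvm.experiment.run_experiment. Enforced by borvm.experiment.validate_report (required keys and basic types).",
  "type": "object",
  "required": [
    "config",
    "seed",
    "cohort",
    "chi_square",
    "bo",
    "best_kernel",
    "test_confusion_matrix",
    "test_metrics",
    "versions"
  ],
  "properties": {
    "config": {"type": "object"},
    "seed": {"type": "integer"},
    "cohort": {
      "type": "object",
      "required": ["n_records", "n_died", "n_train", "n_test", "feature_order"]
    },
    "chi_square": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["statistic", "dof", "p_value"]
      }
    },
    "bo": {
      "type": "object",
      "required": ["history", "best_config", "best_objective", "trace", "termination_reason"]
    },
    "best_kernel": {"type": "object", "required": ["family", "gamma"]},
    "n_relevance_vectors": {"type": "integer"},
    "test_confusion_matrix": {"type": "object", "required": ["tp", "fp", "fn", "tn"]},
    "test_metrics": {
      "type": "object",
      "required": ["accuracy", "ppv", "npv", "tpr", "tnr", "f1", "auc"]
    },
    "versions": {"type": "object"}
  }
}
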