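{
  "name": "M4-like (synthetic placeholder)",
  "reference": "failed_pul",
  "logits": {
    "iup": {
      "intercept": -2.090656,
      "log_ratio": 14.553020,
      "log_ratio_sq": -4.977778
    },
    "ep": {
      "intercept": 0.178831,
      "log_hcg1": -0.08,
      "log_ratio": 3.533340,
      "log_ratio_sq": 0.485950
    }
  },
  "note": "SYNTHETIC PLACEHOLDER, not the published M4 coefficients. A deliberately miscalibrated comparator: the M6NP-like placeholder's logits sharpened by 1.4 with the EP logit shifted down (mean shift about -0.55 on the log-odds scale, partly through a small first-hCG term). On descriptive-mode synthetic cohorts it under-predicts EP on average (calibration-in-the-large > 0) with a calibration slope below 1, emulating the qualitative behaviour of an older comparator model."
}
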