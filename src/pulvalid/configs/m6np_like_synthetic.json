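{
  "name": "M6NP-like (synthetic placeholder)",
  "reference": "failed_pul",
  "logits": {
    "iup": {
      "intercept": -1.493326,
      "log_ratio": 10.395014,
      "log_ratio_sq": -3.555556
    },
    "ep": {
      "intercept": 0.145999,
      "log_ratio": 2.523814,
      "log_ratio_sq": 0.347107
    }
  },
  "note": "SYNTHETIC PLACEHOLDER, not the published M6NP coefficients. Same functional form (quadratic polynomial in log hCG ratio, failed PUL reference); coefficients are the Bayes-consistent logits of this package's default cohort simulator, so the model is well calibrated on descriptive-mode synthetic cohorts. Transcribe the published equations into this schema for a real validation."
}
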