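{
  "predictor_name": "qsofa_hbp",
  "coefficients": [
    -4.017173117962832,
    1.206648999293397
  ],
  "covariance": [
    [
      0.0768562435249702,
      -0.025814121085218633
    ],
    [
      -0.025814121085218696,
      0.009983948194670704
    ]
  ],
  "converged": true,
  "n_events": 179,
  "n_total": 794,
  "log_likelihood": -312.6005038052018,
  "categorical": false,
  "levels": null,
  "provenance": "synthetic: trained on the packaged default simulated cohort (n=794, generator seed 20180601); not a clinically validated model"
}
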