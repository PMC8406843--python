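{
  "name": "KO",
  "intercept": -1.993,
  "coefficients": {
    "K01752": 830.2118,
    "K01738": 301.6231,
    "K00175": 6023.7645,
    "K03737": 955.9364,
    "K01006": 253.4848,
    "K01653": -134.3974,
    "K01647": -2850.2412,
    "K15023": -2688.788
  },
  "selection_meta": null
}
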