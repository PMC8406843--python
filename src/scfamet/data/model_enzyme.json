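{
  "name": "enzyme",
  "intercept": -2.562,
  "coefficients": {
    "menI": 1523.4525,
    "tesB": -2669.9255,
    "yciA": 3907.8004,
    "CO dehydrogenase acetyl-CoA synthase complex": 1520.0528
  },
  "selection_meta": null
}
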