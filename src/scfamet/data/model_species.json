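{
  "name": "species",
  "intercept": 0.2773,
  "coefficients": {
    "Coprococcus catus": -750.2988,
    "Firmicutes bacterium CAG:103": 13.6656
  },
  "selection_meta": null
}
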