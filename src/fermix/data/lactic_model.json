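{
  "labels": ["X1", "X2", "X3"],
  "order": "special_cubic",
  "terms": [
    {"name": "X1", "coefficient": 4.172},
    {"name": "X2", "coefficient": 4.187},
    {"name": "X3", "coefficient": 4.215},
    {"name": "X1*X2", "coefficient": -0.023},
    {"name": "X1*X3", "coefficient": 0.006},
    {"name": "X2*X3", "coefficient": -0.029},
    {"name": "X1*X2*X3", "coefficient": -0.042}
  ],
  "units": "g/L",
  "provenance": "published fitted special-cubic model for lactic acid concentration; X1 = P. pentosaceus SL05, X2 = P. acidilactici SL08, X3 = L. plantarum JYLP-002 inoculation proportions"
}
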