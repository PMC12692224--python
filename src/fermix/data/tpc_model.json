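{
  "labels": ["X1", "X2", "X3"],
  "order": "special_cubic",
  "terms": [
    {"name": "X1", "coefficient": 1.136},
    {"name": "X2", "coefficient": 1.217},
    {"name": "X3", "coefficient": 1.198},
    {"name": "X1*X2", "coefficient": 0.304},
    {"name": "X1*X3", "coefficient": 0.524},
    {"name": "X2*X3", "coefficient": 0.201},
    {"name": "X1*X2*X3", "coefficient": 3.100}
  ],
  "units": "mg GAE/mL",
  "provenance": "published fitted special-cubic model for total phenolic content; X1 = P. pentosaceus SL05, X2 = P. acidilactici SL08, X3 = L. plantarum JYLP-002 inoculation proportions"
}
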