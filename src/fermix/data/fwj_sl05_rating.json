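{
  "attributes": ["appearance", "aroma", "taste", "typicality"],
  "grades": ["excellent", "good", "general", "worse"],
  "rating_matrix": [
    [0.7, 0.2, 0.1, 0.0],
    [0.8, 0.2, 0.0, 0.0],
    [0.7, 0.1, 0.1, 0.1],
    [0.6, 0.2, 0.2, 0.0]
  ],
  "weights": [0.2, 0.25, 0.3, 0.25],
  "grade_scores": [100, 75, 50, 25],
  "provenance": "published worked example for sample FWJ-SL05; rows are attributes (the source prints the transpose, grade-major). Note: the source's prose reports appearance counts 7/1/2/0 of 10 panelists, which normalize to (0.7, 0.1, 0.2, 0.0), but its printed matrix row is (0.7, 0.2, 0.1, 0.0); the printed matrix (which reproduces the published score 88.5) is transcribed here verbatim."
}
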