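{
  "gcms_knn": {
    "description": "Reference whole-cohort confusion counts for the GC-MS k-NN classifier (65 sweat samples; CO = negative, CRC = positive) and the metric panel they imply, in percent rounded to one decimal.",
    "counts": {"tn": 30, "fp": 4, "fn": 8, "tp": 23},
    "expected": {
      "accuracy": 81.5,
      "CO": {"sensitivity": 88.2, "specificity": 74.2, "precision": 78.9, "f1": 83.3},
      "CRC": {"sensitivity": 74.2, "specificity": 88.2, "precision": 85.2, "f1": 79.3}
    }
  },
  "enose_lda": {
    "description": "Reference confusion counts for the E-nose LDA classifier (68 sweat samples, one misclassification per group) and the implied rates in percent.",
    "counts": {"tn": 34, "fp": 1, "fn": 1, "tp": 32},
    "expected": {
      "accuracy": 97.1,
      "co_rate": 97.1,
      "crc_rate": 97.0,
      "fp_rate": 2.9,
      "fn_rate": 3.0
    }
  }
}
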