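{
  "comment": "Per-position mismatch penalty weights for the 0-100 single-site off-target score; position 1 = PAM-distal. The 20-mer vector is the experimentally derived SpCas9 mismatch penalty matrix of Hsu et al. 2013 (Nat Biotechnol); the 21-mer vector extends it with a zero penalty at the extra PAM-distal position for 21-nt SaCas9 protospacers.",
  "weights": {
    "20": [0.0, 0.0, 0.014, 0.0, 0.0, 0.395, 0.317, 0.0, 0.389, 0.079, 0.445, 0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583],
    "21": [0.0, 0.0, 0.0, 0.014, 0.0, 0.0, 0.395, 0.317, 0.0, 0.389, 0.079, 0.445, 0.508, 0.613, 0.851, 0.732, 0.828, 0.615, 0.804, 0.685, 0.583]
  }
}
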