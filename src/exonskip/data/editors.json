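{
  "comment": "C>T base editor definitions. Efficiency profiles are APPROXIMATE values digitized from published editing-window figures (Kim et al. 2017, Nat Biotechnol); positions are 1-based, PAM-distal = 1. Only primary PAMs are used for guide design by default; secondary PAMs are recognised with lower efficiency and used for off-target scanning.",
  "editors": [
    {
      "name": "SpCas9-BE3",
      "pam": "NGG",
      "secondary_pams": ["NAG"],
      "protospacer_length": 20,
      "profile": {"4": 0.26, "5": 0.38, "6": 0.43, "7": 0.39, "8": 0.29, "9": 0.12}
    },
    {
      "name": "SpCas9-VQR-BE3",
      "pam": "NGA",
      "secondary_pams": ["NAG"],
      "protospacer_length": 20,
      "profile": {"4": 0.20, "5": 0.31, "6": 0.34, "7": 0.29, "8": 0.19, "9": 0.08}
    },
    {
      "name": "SpCas9-VRER-BE3",
      "pam": "NGCG",
      "secondary_pams": [],
      "protospacer_length": 20,
      "profile": {"4": 0.16, "5": 0.26, "6": 0.30, "7": 0.25, "8": 0.15}
    },
    {
      "name": "SaCas9-KKH-BE3",
      "pam": "NNNRRT",
      "secondary_pams": [],
      "protospacer_length": 21,
      "profile": {"3": 0.10, "4": 0.18, "5": 0.26, "6": 0.32, "7": 0.35, "8": 0.34, "9": 0.30, "10": 0.24, "11": 0.16, "12": 0.09}
    }
  ]
}
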