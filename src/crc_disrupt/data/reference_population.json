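{
  "n": 200,
  "seed": 7,
  "birth_year": 1970.25,
  "digests": {
    "preset-A": "5165f72df2ee6c68747863e385d819d7f1cfc0d00084daad5e2b0f73388153f9",
    "preset-B": "3b67560742236d5ca79765e88bb494f199dc7f05dd82403c40fb29d932c7b2ca"
  }
}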