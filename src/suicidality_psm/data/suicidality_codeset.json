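{
  "name": "suicidality",
  "allow_overlap": false,
  "subtypes": {
    "ideation": ["R45851"],
    "self_harm": ["R4588", "Z915", "Z9151", "Z9152"],
    "attempt": ["T1491", "T1491XA", "T1491XD", "T1491XS"]
  }
}
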