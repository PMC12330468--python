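[
  {"pattern": "F63*", "category": "disruptive_impulse"},
  {"pattern": "F91*", "category": "disruptive_impulse"},
  {"pattern": "F64*", "category": "gender_dysphoria"},
  {"pattern": "F60*", "category": "personality"},
  {"pattern": "F61*", "category": "personality"},
  {"pattern": "F62*", "category": "personality"},
  {"pattern": "F65*", "category": "personality"},
  {"pattern": "F66*", "category": "personality"},
  {"pattern": "F68*", "category": "personality"},
  {"pattern": "F69*", "category": "personality"},
  {"pattern": "F40*", "category": "anxiety"},
  {"pattern": "F41*", "category": "anxiety"},
  {"pattern": "F32*", "category": "depressive"},
  {"pattern": "F33*", "category": "depressive"},
  {"pattern": "F34*", "category": "depressive"},
  {"pattern": "F30*", "category": "bipolar"},
  {"pattern": "F31*", "category": "bipolar"},
  {"pattern": "F2*", "category": "schizophrenia_spectrum"},
  {"pattern": "F90*", "category": "adhd"},
  {"pattern": "F43*", "category": "trauma_stressor"},
  {"pattern": "F44*", "category": "dissociative"},
  {"pattern": "F42*", "category": "obsessive_compulsive"},
  {"pattern": "F50*", "category": "eating"},
  {"pattern": "F1*", "category": "substance_use"}
]
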