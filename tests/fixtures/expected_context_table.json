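{
  "family_negated": 0,
  "family_not_negated": 148,
  "family_share": 0.04423191870890616,
  "patient_negated": 313,
  "patient_not_negated": 2885,
  "patient_not_negated_share": 0.9021263289555973,
  "total": 3346
}
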