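{
  "description": "Published study-level counts of OTUs whose structural coefficients were statistically different from zero (HPD95% excluding 0), split by sign and trait. 'both' counts OTUs significant for both ADG traits; per-trait counts include the shared ones.",
  "n_otus_analyzed": 946,
  "n_significant_AL": 82,
  "n_significant_R": 80,
  "n_significant_both": 24,
  "n_positive_AL_only": 45,
  "n_positive_R_only": 45,
  "n_positive_both": 14,
  "n_negative_AL_only": 13,
  "n_negative_R_only": 11,
  "n_negative_both": 10
}
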