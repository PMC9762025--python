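{
  "description": "Descriptive statistics of the two growth traits (g/day). effective_sd_AL is the SD back-calculated from the published standardized effects for ADG_AL, which differs from the observed SD in the third decimal.",
  "AL": {"n": 218, "mean": 55.09, "sd": 5.91, "iqr": 7.57},
  "R": {"n": 194, "mean": 38.84, "sd": 5.27, "iqr": 6.89},
  "effective_sd_AL": 5.92
}
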