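{
  "synthetic_spec": "builtin:reference",
  "targets": ["panitumumab"],
  "comparators": ["bevacizumab"],
  "conditions": ["ineffectiveness"],
  "min_reports": 5,
  "z": 1.96,
  "out_dir": "out",
  "seed": 0
}
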