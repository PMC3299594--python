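{
  "schema_version": 1,
  "label": "KBD",
  "n_train": 22615,
  "stats": {
    "Wt": {"mean": 411, "sd": 96},
    "RB": {"mean": 6.1, "sd": 3.3},
    "HBA": {"mean": 3.7, "sd": 1.6},
    "HBD": {"mean": 1.9, "sd": 1.3},
    "SlogP": {"mean": 3.4, "sd": 1.8},
    "TPSA": {"mean": 89, "sd": 33},
    "Rings": {"mean": 4.0, "sd": 1.2},
    "nN": {"mean": 4.3, "sd": 1.8},
    "nO": {"mean": 2.4, "sd": 1.9}
  }
}
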