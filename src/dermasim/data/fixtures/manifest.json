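{
  "cream-ivrt": {
    "seed": 101,
    "replicate_cv": 0.15,
    "n_replicates": 6,
    "mode": "ivrt",
    "vehicle_kind": "emulsion"
  },
  "ointment-ivrt": {
    "seed": 102,
    "replicate_cv": 0.15,
    "n_replicates": 6,
    "mode": "ivrt",
    "vehicle_kind": "suspension"
  },
  "cream-ivpt": {
    "seed": 103,
    "replicate_cv": 0.15,
    "n_replicates": 5,
    "mode": "ivpt",
    "vehicle_kind": "emulsion"
  },
  "ointment-ivpt": {
    "seed": 104,
    "replicate_cv": 0.15,
    "n_replicates": 5,
    "mode": "ivpt",
    "vehicle_kind": "suspension"
  }
}
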