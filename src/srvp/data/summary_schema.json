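{
 "title": "srvp pipeline summary",
 "type": "object",
 "required": [
  "config_hash",
  "seed",
  "n_channels",
  "diameter_amplitude_pct",
  "area_amplitude_pct",
  "sensitivity_ratio",
  "flow_oscillation_pct",
  "per_channel",
  "pulse_wave",
  "intensity"
 ],
 "properties": {
  "config_hash": {"type": "string"},
  "seed": {"type": "integer"},
  "n_channels": {"type": "integer"},
  "diameter_amplitude_pct": {"type": "number"},
  "area_amplitude_pct": {"type": "number"},
  "sensitivity_ratio": {"type": "number"},
  "flow_oscillation_pct": {"type": "number"},
  "per_channel": {"type": "array"},
  "pulse_wave": {"type": "object", "nullable": true},
  "intensity": {"type": "object", "nullable": true}
 }
}
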