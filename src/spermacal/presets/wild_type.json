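{
  "name": "wild_type",
  "baseline": 1.0,
  "noise_sd": 0.02,
  "onset_delay": 60.0,
  "pulse_period": 25.0,
  "pulse_amplitude": 0.4,
  "ramp_rate": 0.004,
  "wave_speed": 0.1,
  "pulse_tau": 6.0,
  "valve_regime": "entry_spike_then_quiet",
  "entry_frame": 30,
  "neck_close_frame": 70,
  "valve_open_frame": 330,
  "valve_close_frame": 390,
  "exit_outcome": "exited_successfully"
}
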