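{
  "name": "gsa1_gf",
  "baseline": 1.0,
  "noise_sd": 0.02,
  "onset_delay": 20.0,
  "pulse_period": 40.0,
  "pulse_amplitude": 0.15,
  "ramp_rate": 0.002,
  "wave_speed": 0.1,
  "pulse_tau": 8.0,
  "valve_regime": "pulsing_with_bag",
  "entry_frame": 30,
  "neck_close_frame": 75,
  "valve_open_frame": 450,
  "valve_close_frame": 520,
  "exit_outcome": "exited_successfully"
}
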