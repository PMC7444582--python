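{
  "name": "kin1_kd",
  "baseline": 1.0,
  "noise_sd": 0.02,
  "onset_delay": 0.0,
  "pulse_period": 25.0,
  "pulse_amplitude": 0.0,
  "ramp_rate": 0.0,
  "wave_speed": 0.1,
  "pulse_tau": 6.0,
  "valve_regime": "suppressed",
  "entry_frame": 30,
  "neck_close_frame": 80,
  "valve_open_frame": null,
  "valve_close_frame": null,
  "exit_outcome": "trapped"
}
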