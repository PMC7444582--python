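{
  "name": "pde6_kd",
  "baseline": 1.0,
  "noise_sd": 0.02,
  "onset_delay": 80.0,
  "pulse_period": 35.0,
  "pulse_amplitude": 0.3,
  "ramp_rate": 0.003,
  "wave_speed": 0.08,
  "pulse_tau": 7.0,
  "valve_regime": "entry_spike_then_quiet",
  "entry_frame": 30,
  "neck_close_frame": 90,
  "valve_open_frame": null,
  "valve_close_frame": null,
  "exit_outcome": "trapped"
}
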