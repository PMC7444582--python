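{
  "name": "empty_pulsing",
  "baseline": 1.0,
  "noise_sd": 0.02,
  "onset_delay": 10.0,
  "pulse_period": 50.0,
  "pulse_amplitude": 0.6,
  "ramp_rate": 0.0,
  "wave_speed": 0.15,
  "pulse_tau": 8.0,
  "valve_regime": "pulsing_with_bag",
  "entry_frame": null,
  "neck_close_frame": null,
  "valve_open_frame": null,
  "valve_close_frame": null,
  "exit_outcome": null
}
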