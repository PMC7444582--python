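{
  "name": "kin2_kd",
  "baseline": 1.0,
  "noise_sd": 0.02,
  "onset_delay": 5.0,
  "pulse_period": 30.0,
  "pulse_amplitude": 0.5,
  "ramp_rate": 0.0,
  "wave_speed": 0.2,
  "pulse_tau": 5.0,
  "valve_regime": "pulsing_with_bag",
  "entry_frame": 30,
  "neck_close_frame": 60,
  "valve_open_frame": null,
  "valve_close_frame": null,
  "exit_outcome": "trapped"
}
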