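# spermacal

Quantification of GCaMP Ca²⁺ dynamics during oocyte transits through the
*C. elegans* spermatheca — the contractile tube (distal neck, central bag,
sp-ut valve) where oocytes are fertilized and pushed into the uterus.

The package covers the full analysis chain used on time-lapse widefield
recordings of `fln-1p::GCaMP3` animals, plus a synthetic movie generator so
that every stage can be validated against known ground truth without any
imaging data:

- **Simulation** (`spermacal.synthetic_data`) — 1-D spatiotemporal Ca²⁺
  fields F(x, t) = B + ε + Σᵢ A₀(1 + r·(tᵢ − t_entry))·g((t − tᵢ − x/v)/τ)
  with unit-peak Gaussian pulses propagating distal→proximal at speed *v*,
  onset schedule tᵢ = t_entry + D + i·P, genotype-like presets
  (`wild_type`, `gsa1_kd`, `kin1_kd`, `kin2_kd`, `gsa1_gf`, `pde6_kd`,
  `empty_pulsing`), four sp-ut-valve regimes, and TIFF rendering with an
  invertible intensity map.
- **Image I/O + registration** (`spermacal.image_io`) — multi-page grayscale
  TIFF stacks; rigid integer-pixel registration to frame 0 by exhaustive
  zero-normalized cross-correlation.
- **Traces and kymograms** (`spermacal.trace_pipeline`) — per-frame ROI
  means; F/F₀ normalization to the mean of the 30 frames immediately
  preceding oocyte entry; column-mean kymograms (one row per frame) in which
  a propagating wave appears as a streak of slope 1/v.
- **Peak metrics** (`spermacal.peak_metrics`) — 5-point moving-average
  smoothing; peak detection by topographic prominence (≥ 0.1 F/F₀ units)
  and width at half prominence (≥ 5 samples); peak count, peaks per second
  of transit, time after entry to half-maximal and maximal signal, and the
  variance of the first derivative as a flatness statistic.
- **Transit annotation** (`spermacal.transit_annotation`) — entry/dwell/
  exit/total times from the four annotated timepoints (dwell may be
  negative), phenotype classification (exits successfully / trapped /
  returns to gonad arm / valve opens, no exit), population-assay tables.
- **Group statistics** (`spermacal.group_stats`) — two-sided Fisher exact
  test by hypergeometric enumeration (probability-mass rule) and the
  one-way ANOVA omnibus F, with significance stars at 0.05/0.01/0.005/0.0001.

## Worked example

```python
from spermacal import (load_preset, simulate_field, render_movie, ROISpec,
                       extract_trace, normalize_trace, compute_metrics)

preset = load_preset("kin2_kd")               # rhythmic pulses every 30 s
field, truth = simulate_field(preset, duration=600, seed=1)
stack = render_movie(field, height=20, width=80)
trace = normalize_trace(extract_trace(stack, ROISpec.full_frame(stack)),
                        entry_frame=preset.entry_frame)
trace.events = truth.events
print(compute_metrics(trace))
```

prints

```
PulseMetrics(n_peaks=19, peaks_per_second=0.0334, t_half_max=0.0,
             t_max=278.0, deriv_variance=1.19e-03)
```

All 19 simulated pulses are detected; 0.0334 peaks/s matches the 1/30 s⁻¹
pulse rate of the preset; t_max = 278 s is the time from entry to the
tallest peak; and the derivative variance is two orders of magnitude above
that of a flat (`gsa1_kd`-like) trace at the same noise level, which is how
"flat" traces are told apart quantitatively.

The same pipeline is available from the shell (`spermacal simulate`,
`register`, `extract`, `peaks`, `transits`, `stats`) and as narrative
scripts under `examples/`.

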