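# Methods

## The measurement problem

During an ovulation, an oocyte is pulled into the *C. elegans* spermatheca,
fertilized, and expelled into the uterus through the sp-ut valve.
Coordinated Ca²⁺ signaling in the myoepithelial bag and valve drives the
contractions; genetic perturbations (e.g. of Gα_s–PKA signaling) change the
Ca²⁺ dynamics and the transit outcome.  The package quantifies those
dynamics from time-lapse GCaMP movies: a normalized intensity trace per
spermatheca, a space–time kymogram, peak-based pulse metrics, transit
times from manually annotated event frames, and group statistics.

## Trace extraction and normalization

The per-frame signal is the arithmetic mean of a rectangular ROI covering
the spermatheca.  Fluorescence is reported as F/F₀ with F₀ the mean of the
30 frames immediately preceding the start of oocyte entry.  The baseline is
entry-anchored (the 30 frames *before entry*, not the first 30 of the
recording); when fewer pre-entry frames exist the window shrinks to what is
available and a warning is raised, so short fixtures remain usable.  An
entry at frame 0 or a zero baseline is an error.  Two identities pin the
implementation down: the baseline window of F/F₀ averages exactly 1, and
F/F₀ is invariant to scaling all pixels by any c > 0.

Kymograms average each ROI column over the ROI rows, giving one row per
frame.  Because all columns have equal weight, each kymogram row's mean
equals that frame's ROI mean to machine precision.  Kymograms are computed
on raw intensities by default, with an optional normalized variant
(`normalize_by=F0`) since either convention is defensible for display.

## Registration

The acquisition protocol paralyzes animals, leaving only small rigid
drifts.  Registration is therefore integer-pixel translation to frame 0:
for each frame the (dy, dx) within ±max_shift maximizing zero-normalized
cross-correlation on the overlap with frame 0 is chosen, ties broken by
smallest |dy| + |dx| then lexicographically, and exposed edge pixels are
filled with the frame median (a zero fill would bias ROI means downward).
Constant frames cannot be correlated and keep shift (0, 0) with a warning.
Integer-only translation keeps the operation exactly invertible and hence
exactly testable; sub-pixel and non-rigid registration are out of scope.

## Peak detection and pulse metrics

Traces are smoothed with a centered 5-point moving average (edges truncate
to the available samples; output length equals input length).  A peak is a
local maximum — a flat plateau counts once, at its middle sample,
left-middle on even plateaus — kept when its topographic prominence is at
least 0.1 F/F₀ units and its width at half prominence is at least
5 samples.  Prominence is the peak value minus the higher of the two
flanking bases, each base being the signal minimum between the peak and the
nearer of the signal end or the next strictly higher sample; width is the
interpolated horizontal extent at height (value − prominence/2).  "Units"
means normalized F/F₀ units for prominence and samples for width (samples
equal seconds at the 1 frame/s acquisition rate).  The implementation is
validated sample-for-sample against an O(n²) brute-force oracle and against
scipy's independent prominence/width machinery.

Metrics are computed on the smoothed trace restricted to the transit window
[entry, valve closure], falling back to the recording end when the valve
never closes (peak counting for occupied spermathecae is transit-bounded by
default).  peaks_per_second divides the count by the same duration, so rate
differences reflect transit duration.  t_max is the time from entry to the
highest-valued detected peak (earliest wins on ties); t_half_max is the
time from entry to the first smoothed sample at or above half that peak's
absolute value — a first-crossing semantics.  Whether "half max" should be
halfway above baseline instead is a genuine ambiguity; the absolute
convention is the default and `half_max_mode="baseline_subtracted"`
thresholds at 1 + (peak − 1)/2.  Both times are null when no peak survives
the filters.  The flatness statistic is the sample variance (n − 1
denominator) of successive differences of the unsmoothed normalized trace;
any linear ramp scores exactly 0.

## Transit times, phenotypes, populations

Four annotated frames define the intervals: entry = neck closure − entry
start; dwell = valve opening − neck closure (negative when the valve opens
before the neck has closed — a real phenotype, reported as-is);
exit = valve closure − opening; total = closure − entry start, so
entry + dwell + exit = total whenever all four exist.  Annotations are
stored as frame indices and converted by dt, keeping them frame-rate
independent; they are manual input, not inferred from pixels.

Phenotype classification is a fixed rule order: reflux into the gonad arm
dominates (re-entry after reflux is not given precedence — the annotations
do not encode ordering); otherwise an opened valve with a confirmed exit is
a success; an opened valve without exit is its own category; otherwise
trapped.  An exit flag without a valve opening is rejected as inconsistent.
Population assays use four categories, with embryo fragments and
liquid-filled spermathecae pooled into one category because downstream
statistics always compare unoccupied against the pooled rest.

## Statistics

The 2×2 comparison (unoccupied vs rest, or exited vs rest) uses the
two-sided Fisher exact test with the probability-mass convention: the sum
of hypergeometric probabilities, over all tables with the observed margins,
that do not exceed the observed table's probability (relative tie tolerance
1e-7).  Factorials are computed via log-gamma so large margins stay stable.
Continuous metrics use the one-way ANOVA omnibus F with p from the F upper
tail; zero within-group variance with between-group spread reports
F = +inf, p = 0, and all-identical data are rejected.  Stars follow the
0.05 / 0.01 / 0.005 / 0.0001 thresholds.  Tukey HSD post-hoc p-values are
deliberately not implemented; pairwise F (or Fisher) tests with an optional
Bonferroni correction are provided instead, since studentized-range
quantiles add heavy numerics without touching the package's core content.

## The simulator and what it does (not) show

The generator emulates: a baseline-normalized signal near 1.0, additive
i.i.d. Gaussian noise (a desk-scale stand-in for shot-noise-dominated
widefield baselines), distal→proximal pulse trains with onset delay D,
period P, linear amplitude ramp r (the simplest model of signal that keeps
increasing until peaking), Gaussian pulse shape τ, and wave speed v; and a
valve block occupying the proximal 10% of columns (4 valve cells vs 24 bag
cells) in one of four regimes: entry spike then quiet (wild-type-like),
sustained high (gsa-1-knockdown-like), suppressed, or pulsing in register
with the bag (kin-2-knockdown-like and the empty-spermatheca oscillator).
The spatial convention is distal at column 0, valve at the right; source
descriptions of orientation are contradictory, so the package fixes this
one and keeps it throughout.

Preset parameter values (periods, amplitudes, delays) are this package's
own choices of realistic dynamics — no quantitative per-genotype values are
published — chosen once: e.g. the rhythmic preset pulses every 30 s at
amplitude 0.5 with σ = 0.02 noise, the flat presets have zero pulse
amplitude at equal noise.  The generator does **not** model IP₃/ER
biophysics, 2-D tissue geometry, photobleaching, motion blur, or occlusion
by the embryo; passing recovery tests therefore demonstrates the
correctness of the measurement code under the stated signal model, not
performance on real movies.

Rendering maps normalized values affinely to gray levels
(gray = round(100·value) by default, recorded in the stack provenance so it
is invertible) and replicates field columns into pixel blocks differing by
at most one pixel in width; ROI means of rendered frames reproduce the
field's spatial means within the 0.5-gray-level quantization bound.

## Numerical and testing choices

Simulations are deterministic given (preset, duration, seed) via numpy's
Generator; ground truth lists exactly the pulse onsets emitted.  Problem
sizes in the test and acceptance runs — 600-frame traces, 48×48
registration fixtures, 100-seed ensembles, margins ≤ 30 for Fisher
enumeration cross-checks — were chosen so the whole suite completes in
seconds while every ensemble criterion (≥95% recovery, 100/100 orderings)
remains statistically meaningful.  The peak finder and Fisher test are
validated against independent oracles (brute force and scipy); the oracles
live in the test suite and share no code with the implementations.
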