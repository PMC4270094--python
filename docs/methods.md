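# Methods

This note documents the models, conventions and numerical choices behind
`ripplelock`, and what the synthetic-data tests do and do not establish
about behavior on recorded data.

## Scope and signal model

The package analyzes a single local-field-potential (LFP) channel with
paired single-cell spike timestamps and a treadmill speed trace, the typical
output of a juxtacellular recording session in hippocampal CA1. Four
oscillation bands are built in: theta (5–10 Hz), gamma (25–90 Hz), epsilon
(90–130 Hz, during running) and ripple (90–200 Hz, during rest). Epsilon and
ripple overlap spectrally on purpose — they are distinguished by behavioral
state, not spectrum. Phase follows the trough-zero convention throughout:
0° is the cycle trough, 180° the peak; ascending limb 0→180°, descending
180→360°.

## Signal processing

**Filtering.** All band-pass filtering is a 4th-order Butterworth applied
forward–backward (`sosfiltfilt`), i.e. zero-phase. Phase fidelity is the
binding constraint: trough and peak times anchor the phase convention, and
any group delay would translate directly into a preferred-phase bias. The
forward–backward pass squares the magnitude response, so passband corners
sit at −6 dB rather than −3 dB; the synthetic generator compensates planted
event amplitudes for this response when calibrating SNR (below). Filter
edge transients span a few hundred samples; analyses that touch trace edges
(landmark phase, triggered averages) flag or drop those spans.

**Downsampling** uses zero-phase FIR decimation, in cascaded stages of ≤10×
for large factors (e.g. 20× from a 20 kHz acquisition). Theta analyses run
on a downsampled trace, mirroring common practice for slow bands.

**Envelopes** are the magnitude of the analytic (Hilbert) signal of the
band-passed trace. For a pure tone of amplitude A this returns A to within
a few percent away from edges, and it upper-bounds the rectified signal.

**Filterbank time–frequency maps** use 4 Hz-wide bands stepped every 2 Hz
from 10 to 200 Hz (96 bands). Each band is envelope-detected; "power" is
the squared envelope by default (a config switch selects the envelope
itself), then z-scored per band over the whole usable trace (per-state
normalization is available as an option). Note that a 4 Hz-wide band cannot
follow amplitude modulation faster than ~2 Hz, so theta-rate (8 Hz)
modulation of fast-band power appears attenuated in these maps; its *phase*
(where in the theta cycle fast power peaks) is preserved, which is what
trough-triggered averaging reads out.

## Event detection

Ripple-like transients are detected on the ripple-band envelope with a dual
threshold: candidate excursions must reach 5 SD and are extended outward to
the 2 SD crossings, which define the event boundaries. Thresholds are in SD
units of the envelope **above its mean** (`z = (env − mean)/SD`). The
envelope mean/SD are estimated from all samples inside the supplied
behavioral epochs, event samples included; this overestimates the baseline
slightly when events are dense (an iterative exclusion re-estimate is not
provided because at realistic event densities — a few seconds of event time
per several hundred seconds of rest — the bias is ≪1 SD). Nearby
supra-threshold excursions closer than `merge_gap` (default 10 ms) are
merged and events shorter than `min_duration` (default 20 ms) are dropped;
both defaults exist to keep one physiological event from being counted
twice across an envelope dip, and both are exposed in the configuration.
Because thresholds are relative, detection is exactly invariant to
rescaling the raw trace.

Behavioral segmentation thresholds the speed trace (default threshold 1.0
in trace units — synthetic traces are bimodal around it; real data need a
calibrated value) and keeps run intervals >20 s and rest intervals >200 s.
Sub-minimum intervals are discarded, never merged across interruptions.

## Phase assignment and circular statistics

The default phase extractor interpolates linearly between detected cycle
landmarks: each trough maps to 0° (mod 360) and each peak to 180°, so an
asymmetric cycle (hippocampal theta is famously sawtooth-like) still maps
its ascending limb exactly onto 0–180°. Analytic-signal phase (shifted so a
tone's troughs read 0°) is available as an alternative; the two differ on
asymmetric waveforms, which is why both are provided and labeled. Samples
before the first and after the last landmark are NaN and spikes there are
excluded (with counts reported).

Per-cell phase locking is summarized by the resultant vector
`r·e^{iθ̄} = (1/n) Σ e^{iθ_j}`: r is the modulation strength (0 = none,
1 = all spikes at one phase) and θ̄ the preferred phase. Uniformity is
tested with the Rayleigh statistic Z = n r² using the standard finite-n
corrected p-value `exp(√(1+4n+4(n²−R²)) − (1+2n))`; n ≥ 5 is required.
Group mean directions are compared with the Watson–Williams circular
one-way ANOVA (F-statistic with the 1 + 3/(8κ̂) correction, κ̂ from the
pooled resultant via Fisher's approximation). The test assumes von-Mises
samples with adequate shared concentration; a warning is emitted when the
pooled within-group resultant is below 0.45 or any group has n < 5.

Across cells, a class's preferred phase is the circular mean of per-cell
mean phases with circular SD as dispersion — each cell weighted equally
regardless of spike count. When classes are compared with Watson–Williams
inside the pipeline's cohort report, pooled spike phases are used (the
per-cell route with 2–12 cells per class sits below the test's small-sample
comfort zone and triggers the warning; both routes are available in the
API).

## Event-related rates

Rates are spike counts over interval durations. Event-related modulation is
tested by Monte Carlo: the in-event spike count is compared against
surrogates that either redraw all spike times uniformly within the
behavioral state (spike shuffle) or uniformly reposition the events within
it, preserving durations and non-overlap (event shuffle). The p-value is
`(k+1)/(N+1)` on the more extreme tail, doubled and capped at 1; the
default is N = 1000 surrogates with the seed recorded in the result. At
N = 1000 the attainable two-sided levels include 0.05 exactly and the
test's measured type-I error is ≈0.04 at α = 0.05 (slightly conservative,
as doubled-tail discrete p-values are); at a few hundred surrogates the
0.025 tail quantile is not attainable and the conservatism grows — hence
the 1000-surrogate default.

Participation is the fraction of events containing ≥1 spike; the
early-spike fraction is the pooled fraction of in-event spikes preceding
the envelope peak. A doublet is ≥2 spikes between two consecutive
ripple-band troughs inside one event — trough-to-trough is the unique
parameter-free cycle partition consistent with the trough-zero phase
convention. The peri-event histogram uses normalized time: each event's
before/during/after spans (flanks twice the event duration) are split into
40/20/40 bins; the reported value per bin is the mean spike count per event
(≈ spiking probability for these short bins), so the 20 "during" bins sum
exactly to the mean in-event spike count.

## Core frequency

Three per-event estimators, all on the 90–200 Hz filtered signal *within
the detected event boundaries* (the low-amplitude envelope tails outside
the 2 SD crossings are below the noise floor and would corrupt
interval-based estimates):

* **zero_crossing** — half the inverse mean inter-zero-crossing interval,
  crossings located by linear interpolation; exact-zero samples inherit the
  previous sign so windowed endpoints cannot manufacture crossings.
* **peak_interval** — inverse mean interval between positive local maxima,
  with parabolic sub-sample refinement of peak positions.
* **wavelet** (default) — complex Morlet scalogram (bandwidth parameter 5,
  center-frequency parameter 1) on a 90–200 Hz grid at 1 Hz spacing; the
  event's core frequency is the grid frequency of the global magnitude
  maximum. When estimating through the pipeline, the segment is extracted
  with half-event context padding to suppress scalogram edge effects, but
  the maximum is taken over the event span only.

On synthetic events the three agree to ~1 Hz median. Events with vs.
without a given cell's spikes are compared with the two-sample rank-sum
(Mann–Whitney) test by default — the two event sets are independent, so a
paired signed-rank test is not appropriate, though it is available via an
argument for comparability.

## Synthetic data: what it emulates and what it does not

The generator produces: 1/f^α Gaussian background (α = 1 by default, a
standard LFP surrogate — the spectral shape, not a biophysical model);
continuous rhythms planted as `−cos(phase)` within epochs, optionally
amplitude-coupled to a carrier rhythm's phase (fast-band power maximal at a
set carrier phase, emulating theta-nested fast oscillations); transient
Hann-enveloped bursts with a planted core frequency (40–150 ms, 90–200 Hz
by default); piecewise-constant speed traces; and spike trains generated by
Bernoulli thinning at LFP resolution of a rate
`base_rate × vonMises(phase; θ₀, κ) × event_gain`, with a 2 ms refractory
default and optional doublets (a second spike 3–5 ms after a cycle's first
spike, confined to one fast cycle).

**SNR calibration.** Planted event amplitudes are specified in SD units of
the ripple-band envelope *as the detector measures it*: the requested level
is first expressed against the clean background envelope, the amplitude is
divided by the detection filter's response at the event's core frequency
(so band-corner events reach the same in-band level), and the level is then
re-expressed against the envelope of the composed trace, whose SD the
planted events themselves inflate. Without this two-pass calibration an
"8 SD" event near 90 or 200 Hz lands at ~4–5 detector SD and the stated
simulation condition would be silently violated.

**Boundary ground truth.** For a Hann envelope of peak s SD, the 2 SD
crossing sits `d/(2π)·arccos(1−4/s)` inside each planted edge — for an 8 SD,
100 ms event that is ~33 ms per side. Detector boundary accuracy is
therefore scored against the analytically predicted edge-threshold crossing
of the planted envelope (with the background floor removed in quadrature),
which is the quantity the 2 SD rule defines — not against the full planted
extent, which no envelope-threshold detector can recover. Measured boundary
error is ~4–6 ms mean at 8 SD.

**Not emulated:** sharp-wave (stratum radiatum) low-frequency components,
multi-channel laminar structure, non-Gaussian or nonstationary background,
spike waveform shape, theta frequency drift, and behavioral transitions
with realistic speed dynamics. Passing the synthetic suites therefore
establishes the *correctness of the computations* under the stated
statistical model, not detector performance on recorded data, where
baseline nonstationarity and sharp-wave contamination dominate error
budgets.

**Problem sizes.** Synthetic sessions default to 1250 Hz sampling. All
analyzed bands lie below 200 Hz, and theta analysis conventionally runs on
a ~1 kHz downsampled trace anyway, so simulating at a 12–20 kHz acquisition
rate would only slow every test without changing what the analysis sees.
Calibration suites use 300 s sessions, 20–100 events, 200–1000 Monte-Carlo
repetitions — sizes at which the binomial error of a measured rate (~1.5
percentage points at 200 repetitions) is small against the tolerance bands
being checked.

## Pipeline and reproducibility

`run_pipeline` chains simulate → detect → phases → rates → corefreq →
report; each stage reads and writes plain files in the output directory so
stages can be re-run independently (the CLI exposes them as verbs). Every
source of randomness derives from the single config seed via named
`SeedSequence` streams, and result tables are byte-identical across reruns
of the same config: every table carries a header with the package version,
seed and a hash of the analysis parameters (the output path is excluded
from the hash). Cohort pairwise p-values are reported unadjusted, with an
optional Holm adjustment behind a config flag.

## Known limitations

* The landmark phase extractor inherits landmark noise at low SNR; at
  ripple frequencies and 1250 Hz sampling, phase is additionally quantized
  at ~40°/sample, which leaves class-mean comparisons intact but depresses
  single-cell r slightly (~2%).
* The envelope-SD baseline includes event samples (documented bias, small
  at realistic event densities).
* Watson–Williams on per-cell means with n < 5 cells per class is reported
  with a warning but is, as in the literature it mirrors, underpowered and
  approximate.
* Doublet insertion biases a doublet-firing cell's apparent preferred
  phase toward later phases (the companion spike lands 150–250° after the
  first at ripple frequencies); this mirrors what happens in real
  doublet-firing cells but should be remembered when reading single-cell
  preferred phases.
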