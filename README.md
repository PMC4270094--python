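# ripplelock

Oscillation detection and spike–LFP phase-coupling analysis for hippocampal
electrophysiology, with a synthetic ground-truth generator.

## The problem

Hippocampal interneurons time their firing to network oscillations — theta
(5–10 Hz) and theta-nested epsilon (90–130 Hz) waves during running,
sharp-wave ripples (90–200 Hz) during rest. Characterizing a recorded cell
means answering, quantitatively: *when* in the oscillatory cycle does it
fire, *how strongly* is it modulated, does it fire *more or less* during
transient events than a chance model allows, and does its participation
depend on an event's intra-event ("core") frequency? `ripplelock`
implements that analysis chain as a tested, reusable library for anyone
working with single-cell spike trains paired with an LFP channel —
juxtacellular, tetrode or silicon-probe data alike — plus a synthetic
LFP/spike generator so every stage can be verified against known ground
truth without any recorded data.

## What it computes

* **Signal processing** — zero-phase Butterworth band-pass, anti-aliased
  decimation, Hilbert envelopes, a 10–200 Hz narrow-band filterbank
  (4 Hz bands, 2 Hz steps) with z-scored power, and trigger-aligned
  time–frequency averaging for cross-frequency structure.
* **Event detection** — run/rest segmentation from a speed trace (>20 s
  run, >200 s rest minimums) and dual-threshold ripple detection: envelope
  excursions ≥5 SD, boundaries at the 2 SD crossings.
* **Phase coupling** — spike phases under the trough-zero convention
  (0° = trough, 180° = peak), summarized by the resultant vector

      r·e^{iθ̄} = (1/n) Σ_j e^{iθ_j}

  with r ∈ [0, 1] the modulation strength and θ̄ the preferred phase;
  Rayleigh test of uniformity (Z = n r², finite-n corrected p) and the
  Watson–Williams circular ANOVA for comparing mean directions.
* **Rate dynamics** — in/out-of-event firing rates with spike-shuffle and
  event-shuffle randomization tests (p = (k+1)/(N+1), two-sided), event
  participation, early-spike fraction, within-cycle spike doublets, and
  40/20/40-bin normalized peri-event histograms.
* **Core frequency** — three per-event estimators (zero-crossing,
  peak-interval, complex-Morlet 'cmor5-1' scalogram peak; wavelet is the
  default) and rank-based comparison of core frequencies between events
  with vs. without a cell's spikes.
* **Cohort reporting** — joins per-cell results to a cell-metadata table
  (class/sub-class/immunomarkers; a 27-cell table ships with the package),
  class-level summaries and named statistical comparisons, and the
  phase-lag → latency conversion `Δms = Δ°/360 × 1000/f`.

## Worked example

`examples/05_full_cohort_pipeline.py` simulates a six-cell cohort (two
cells per interneuron class, each pair split into contrasting sub-classes),
runs the full pipeline and prints the cohort report:

```
            rate_run_mean  theta_phase_mean  event_phase_mean  rate_in_mean  participation_mean  doublet_fraction_mean
cell_class
AAC                 25.52            249.01             26.58         14.58                0.50                   0.01
BC                  26.35            313.44             33.49        115.94                1.00                   0.60
Bistrat             32.25            354.18            120.05         34.98                0.81                   0.01

               comparison            test  statistic      p  n1  n2
event_phase_BC_vs_Bistrat watson_williams   223.6981 0.0000 512 156
  rate_run_across_classes           anova    18.4595 0.0206   6   6
```

Reading it: theta preferred phases recover the planted class offsets (AAC
249° vs planted 251°, BC 313° vs 310°, Bistrat 354° vs 0°/360° — all on the
descending limb toward the trough); basket cells fire in every detected
ripple-like event at >100 Hz and carry the doublets, bistratified cells
participate in ~80% of events, and the pooled Watson–Williams test
separates the basket (early, ~55° planted) from bistratified (~126°
planted) event phases decisively. Each `examples/` script is a short
narrative of one capability; all print what the numbers mean.

A thin CLI wraps the same pipeline stages
(`ripplelock simulate|detect|phases|rates|corefreq|report|all -c config.yaml`);
exit codes are 0 (success), 2 (validation), 3 (computation).

## Layout

```
src/ripplelock/     core containers, synth, signal, detect, phase, rates,
                    corefreq, cohort, sessions, pipeline, io, cli
examples/           one narrative script per capability
tests/              unit, property and acceptance suites
docs/methods.md     models, conventions, numerical choices, limitations
```
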