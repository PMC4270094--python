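"""End-to-end orchestration: simulate -> detect -> phases -> rates ->
core frequency -> cohort report.

Every stage reads/writes plain files in ``output_dir`` so the stages can be
run independently (and from the CLI); ``run_pipeline`` chains them all.
Outputs are a pure function of (config, seed): result tables are
byte-identical across reruns with the same config.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .cohort import group_compare, make_cell_table
from .core import LFPRecording, OscillationEvent, SpikeTrain
from .corefreq import CoreFrequencyParams, compare_spike_conditioned, estimate_core_frequencies
from .detect import (
    DetectionParams,
    detect_events,
    find_cycle_landmarks,
    peri_event_windows,
    segment_behavior,
)
from .phase import (
    circular_mean_deg,
    circular_std_deg,
    instantaneous_phase,
    rayleigh_test,
    resultant,
    spike_phases,
    watson_williams,
)
from .rates import (
    detect_doublets,
    early_spike_fraction,
    event_rate_modulation,
    firing_rate,
    participation_fraction,
    peri_event_histogram,
)
from .sessions import CellSpec, cohort_session
from .signal import BANDS, bandpass, downsample

__all__ = [
    "PipelineError",
    "demo_cells",
    "demo_config",
    "run_pipeline",
    "stage_simulate",
    "stage_detect",
    "stage_phases",
    "stage_rates",
    "stage_corefreq",
    "stage_report",
]

_VERSION = "0.1.0"


class PipelineError(ValueError):
    """Configuration or input validation failure."""


def demo_cells() -> list[dict]:
    """A six-cell cohort, one pair per class with contrasting sub-classes.

    Event-phase offsets follow the class ordering the pipeline is meant to
    resolve: basket cells lock early in the fast-event cycle (55 deg),
    bistratified cells later (126 deg); classical axo-axonic cells are not
    event-gated while external ones are.
    """
    return [
        dict(cell_id="sim-cbc", sub_class="C-BC", rate_run=28.0, theta_phase=310.0,
             theta_kappa=0.55, rate_rest=12.0, event_phase=55.0, event_kappa=4.0,
             event_gain=6.0, doublet_prob=0.15),
        dict(cell_id="sim-hbc", sub_class="H-BC", rate_run=28.0, theta_phase=310.0,
             theta_kappa=0.55, rate_rest=12.0, event_phase=55.0, event_kappa=4.0,
             event_gain=10.0, doublet_prob=0.8),
        dict(cell_id="sim-cbistrat", sub_class="C-Bistrat", rate_run=34.0, theta_phase=0.0,
             theta_kappa=0.35, rate_rest=8.0, event_phase=126.0, event_kappa=4.0,
             event_gain=3.0, doublet_prob=0.0),
        dict(cell_id="sim-obistrat", sub_class="O-Bistrat", rate_run=34.0, theta_phase=0.0,
             theta_kappa=0.35, rate_rest=8.0, event_phase=126.0, event_kappa=4.0,
             event_gain=7.0, doublet_prob=0.0),
        dict(cell_id="sim-caac", sub_class="C-AAC", rate_run=27.0, theta_phase=251.0,
             theta_kappa=1.0, rate_rest=6.0, event_phase=130.0, event_kappa=0.0,
             event_gain=1.0, doublet_prob=0.0),
        dict(cell_id="sim-eaac", sub_class="E-AAC", rate_run=27.0, theta_phase=251.0,
             theta_kappa=1.0, rate_rest=6.0, event_phase=120.0, event_kappa=3.0,
             event_gain=4.0, doublet_prob=0.0),
    ]


def demo_config(output_dir, seed: int = 1) -> dict:
    """Bundled demo configuration: synthetic 6-cell cohort session."""
    return {
        "seed": int(seed),
        "output_dir": str(output_dir),
        "simulate": {
            "run_duration": 30.0,
            "rest_duration": 220.0,
            "fs": 1250.0,
            "n_events": 40,
            "snr": 8.0,
            "theta_freq": 8.0,
            "theta_amplitude": 0.2,
            "cells": demo_cells(),
        },
        "behavior": {"speed_threshold": 1.0, "min_run": 20.0, "min_rest": 200.0},
        "detection": {
            "high_threshold": 5.0,
            "edge_threshold": 2.0,
            "min_duration": 0.02,
            "merge_gap": 0.01,
        },
        "phases": {"theta_downsample": 2, "method": "landmark"},
        "rates": {"mode": "spike_shuffle", "n_surrogates": 200, "alpha": 0.05},
        "corefreq": {"method": "wavelet"},
    }


# ---------------------------------------------------------------- plumbing


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        config = rio.load_yaml(config)
    if not isinstance(config, dict):
        raise PipelineError("config must be a mapping or a path to a YAML file")
    for key in ("seed", "output_dir", "simulate"):
        if key not in config:
            raise PipelineError(f"config missing required key {key!r}")
    return config


def _hash(config: dict) -> str:
    # parameter hash covers the analysis parameters, not where they ran
    payload = {k: v for k, v in config.items() if k != "output_dir"}
    return hashlib.md5(yaml.safe_dump(payload, sort_keys=True).encode()).hexdigest()[:10]


def _header(config: dict) -> str:
    return f"# ripplelock v{_VERSION} seed={config['seed']} config_hash={_hash(config)}\n"


def _write_table(path: Path, df: pd.DataFrame, config: dict) -> None:
    with open(path, "w") as f:
        f.write(_header(config))
        df.to_csv(f, sep="\t", index=False, float_format="%.6f")


def _read_table(path: Path) -> pd.DataFrame:
    if not path.exists():
        raise PipelineError(f"missing pipeline input {path}; run the earlier stage first")
    return pd.read_csv(path, sep="\t", comment="#")


def _outdir(config: dict) -> Path:
    out = Path(config["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    return out


def _cell_specs(config: dict) -> list[CellSpec]:
    return [CellSpec(**c) for c in config["simulate"]["cells"]]


def _load_inputs(config: dict):
    out = _outdir(config)
    sig_path = out / "signals.h5"
    if not sig_path.exists():
        raise PipelineError(f"missing {sig_path}; run the simulate stage first")
    signals = rio.load_signals(sig_path)
    if "lfp" not in signals or "speed" not in signals:
        raise PipelineError("signals.h5 must contain 'lfp' and 'speed' channels")
    spikes = {}
    for spec in _cell_specs(config):
        p = out / f"spikes_{spec.cell_id}.tsv"
        if not p.exists():
            raise PipelineError(f"missing spike file {p}")
        spikes[spec.cell_id] = rio.load_spikes(p)
    return signals["lfp"], signals["speed"], spikes


# ------------------------------------------------------------------ stages


def stage_simulate(config) -> None:
    """Generate the synthetic session and write signals, spikes and truth."""
    config = _load_config(config)
    out = _outdir(config)
    sim = dict(config["simulate"])
    cells = [CellSpec(**c) for c in sim.pop("cells")]
    session = cohort_session(int(config["seed"]), cells, **sim)
    rio.save_signals(out / "signals.h5", {"lfp": session.lfp, "speed": session.speed})
    for cid, train in session.spikes.items():
        rio.save_spikes(out / f"spikes_{cid}.tsv", train)
    rio.save_ground_truth(out / "ground_truth.yaml", session.ground_truth)


def _behavior(config: dict, speed):
    b = config.get("behavior", {})
    return segment_behavior(
        speed,
        speed_threshold=b.get("speed_threshold", 1.0),
        min_run=b.get("min_run", 20.0),
        min_rest=b.get("min_rest", 200.0),
    )


def stage_detect(config) -> list[OscillationEvent]:
    """Segment behavior and detect fast events in the rest epochs."""
    config = _load_config(config)
    out = _outdir(config)
    lfp, speed, _ = _load_inputs(config)
    epochs = _behavior(config, speed)
    if not epochs.rest:
        raise PipelineError("no rest epoch satisfies the minimum duration")
    d = config.get("detection", {})
    params = DetectionParams(
        high_threshold=d.get("high_threshold", 5.0),
        edge_threshold=d.get("edge_threshold", 2.0),
        min_duration=d.get("min_duration", 0.02),
        merge_gap=d.get("merge_gap", 0.01),
    )
    events = detect_events(lfp, epochs.rest, params)
    rio.save_events(out / "events.tsv", events)
    _write_table(
        out / "epochs.tsv",
        pd.DataFrame(
            [("run", s, e) for s, e in epochs.run] + [("rest", s, e) for s, e in epochs.rest],
            columns=["state", "start", "end"],
        ),
        config,
    )
    return events


def _load_epochs(out: Path, state: str) -> list[tuple[float, float]]:
    df = _read_table(out / "epochs.tsv")
    sel = df[df["state"] == state]
    return [(float(r["start"]), float(r["end"])) for _, r in sel.iterrows()]


def stage_phases(config) -> pd.DataFrame:
    """Per-cell phase locking during theta (running) and fast events (rest)."""
    config = _load_config(config)
    out = _outdir(config)
    lfp, speed, spikes = _load_inputs(config)
    events = rio.load_events(out / "events.tsv")
    run = _load_epochs(out, "run")
    ph_cfg = config.get("phases", {})
    method = ph_cfg.get("method", "landmark")

    rows = []
    pooled: dict[str, dict[str, np.ndarray]] = {}

    theta_phase = None
    ds_factor = int(ph_cfg.get("theta_downsample", 2))
    if run:
        theta_lfp = bandpass(downsample(lfp, ds_factor), BANDS["theta"])
        theta_phase = instantaneous_phase(theta_lfp, method=method)

    ripple_filtered = bandpass(lfp, BANDS["ripple"])
    ripple_phase = instantaneous_phase(ripple_filtered, method=method)
    event_intervals = [(ev.start, ev.end) for ev in events]

    for cid, train in spikes.items():
        pooled[cid] = {}
        jobs = []
        if theta_phase is not None:
            jobs.append(("theta", theta_phase, run))
        if event_intervals:
            jobs.append(("ripple", ripple_phase, event_intervals))
        for band, phs, epochs_iv in jobs:
            ph, n_excluded = spike_phases(train, phs, epochs_iv)
            pooled[cid][band] = ph
            if ph.size == 0:
                rows.append((cid, band, 0, n_excluded, np.nan, np.nan, np.nan))
                continue
            res = resultant(ph)
            p = rayleigh_test(ph) if ph.size >= 5 else np.nan
            rows.append((cid, band, res.n, n_excluded, res.mean_phase, res.r, p))

    df = pd.DataFrame(
        rows,
        columns=["cell_id", "band", "n_spikes", "n_excluded", "mean_phase", "r", "rayleigh_p"],
    )
    _write_table(out / "phase_results.tsv", df, config)
    for cid, bands in pooled.items():
        parts = [
            pd.DataFrame({"band": band, "phase": ph}) for band, ph in bands.items() if ph.size
        ]
        sp = (
            pd.concat(parts, ignore_index=True)
            if parts
            else pd.DataFrame(columns=["band", "phase"])
        )
        _write_table(out / f"spike_phases_{cid}.tsv", sp, config)
    return df


def stage_rates(config) -> pd.DataFrame:
    """Per-cell rates, event-modulation tests and peri-event histograms."""
    config = _load_config(config)
    out = _outdir(config)
    lfp, speed, spikes = _load_inputs(config)
    events = rio.load_events(out / "events.tsv")
    run = _load_epochs(out, "run")
    rest = _load_epochs(out, "rest")
    r_cfg = config.get("rates", {})
    ripple_filtered = bandpass(lfp, BANDS["ripple"])
    windows = peri_event_windows(events, trace_duration=lfp.duration)

    rows = []
    peh = {}
    for i, (cid, train) in enumerate(spikes.items()):
        rate_run = firing_rate(train, run) if run else np.nan
        sub_seed = int(
            np.random.SeedSequence([int(config["seed"]), 13, i]).generate_state(1)[0]
            % (2**31)
        )
        mod = event_rate_modulation(
            train,
            events,
            rest,
            mode=r_cfg.get("mode", "spike_shuffle"),
            n_surrogates=int(r_cfg.get("n_surrogates", 1000)),
            seed=sub_seed,
            alpha=float(r_cfg.get("alpha", 0.05)),
        )
        part = participation_fraction(train, events)
        early = early_spike_fraction(train, events)
        doublet_frac, intra_rate = detect_doublets(train, events, ripple_filtered)
        peh[cid] = peri_event_histogram(train, windows)
        rows.append(
            (cid, rate_run, mod.rate_out, mod.rate_in, mod.p, mod.direction,
             part, early, doublet_frac, intra_rate)
        )
    df = pd.DataFrame(
        rows,
        columns=["cell_id", "rate_run", "rate_out", "rate_in", "mod_p", "direction",
                 "participation", "early_fraction", "doublet_fraction", "intra_event_rate"],
    )
    _write_table(out / "rate_results.tsv", df, config)
    peh_df = pd.DataFrame({cid: h.probs for cid, h in peh.items()})
    peh_df.insert(0, "bin", np.arange(100))
    _write_table(out / "peri_event_histograms.tsv", peh_df, config)
    return df


def stage_corefreq(config) -> pd.DataFrame:
    """Per-event core frequency and per-cell with/without-spike comparison."""
    config = _load_config(config)
    out = _outdir(config)
    lfp, _, spikes = _load_inputs(config)
    events = rio.load_events(out / "events.tsv")
    params = CoreFrequencyParams(method=config.get("corefreq", {}).get("method", "wavelet"))
    filtered = bandpass(lfp, BANDS["ripple"])
    events = estimate_core_frequencies(filtered, events, params)
    rio.save_events(out / "events.tsv", events)
    rows = []
    for cid, train in spikes.items():
        cmp = compare_spike_conditioned(events, train)
        rows.append(
            (cid, cmp.freqs_with.size, cmp.freqs_without.size, cmp.mean_with, cmp.sd_with,
             cmp.mean_without, cmp.sd_without, cmp.p, cmp.test, cmp.testable)
        )
    df = pd.DataFrame(
        rows,
        columns=["cell_id", "n_with", "n_without", "mean_with", "sd_with",
                 "mean_without", "sd_without", "p", "test", "testable"],
    )
    _write_table(out / "corefreq_comparison.tsv", df, config)
    return df


def _circ_summary(phases_deg: np.ndarray) -> tuple[float, float]:
    if phases_deg.size == 0:
        return np.nan, np.nan
    return circular_mean_deg(phases_deg), circular_std_deg(phases_deg)


def stage_report(config) -> dict[str, pd.DataFrame]:
    """Join per-cell results to metadata; class summaries and comparisons."""
    config = _load_config(config)
    out = _outdir(config)
    specs = _cell_specs(config)
    meta = pd.DataFrame(
        {"cell_id": [s.cell_id for s in specs],
         "sub_class": [s.sub_class for s in specs],
         "cell_class": [s.cell_class for s in specs]}
    )
    phase_df = _read_table(out / "phase_results.tsv").merge(meta, on="cell_id", how="left")
    rate_df = _read_table(out / "rate_results.tsv").merge(meta, on="cell_id", how="left")
    if phase_df["cell_class"].isna().any() or rate_df["cell_class"].isna().any():
        raise PipelineError("result rows reference cells absent from the config cohort")

    summary_rows = []
    for klass, grp in rate_df.groupby("cell_class", sort=True):
        th = phase_df[(phase_df["cell_class"] == klass) & (phase_df["band"] == "theta")]
        rp = phase_df[(phase_df["cell_class"] == klass) & (phase_df["band"] == "ripple")]
        th_mean, th_csd = _circ_summary(th["mean_phase"].dropna().to_numpy())
        rp_mean, rp_csd = _circ_summary(rp["mean_phase"].dropna().to_numpy())
        summary_rows.append(
            (klass, len(grp),
             grp["rate_run"].mean(), grp["rate_run"].std(ddof=0),
             th_mean, th_csd, th["r"].mean(),
             grp["rate_in"].mean(), grp["rate_out"].mean(),
             rp_mean, rp_csd, rp["r"].mean(),
             grp["participation"].mean(), grp["early_fraction"].mean(),
             grp["doublet_fraction"].mean(), grp["intra_event_rate"].mean())
        )
    summary = pd.DataFrame(
        summary_rows,
        columns=["cell_class", "n_cells", "rate_run_mean", "rate_run_sd",
                 "theta_phase_mean", "theta_phase_csd", "theta_r_mean",
                 "rate_in_mean", "rate_out_mean",
                 "event_phase_mean", "event_phase_csd", "event_r_mean",
                 "participation_mean", "early_fraction_mean",
                 "doublet_fraction_mean", "intra_event_rate_mean"],
    )

    # pooled spike phases per class for the circular comparison
    pooled: dict[str, np.ndarray] = {}
    for klass in meta["cell_class"].unique():
        parts = []
        for cid in meta[meta["cell_class"] == klass]["cell_id"]:
            sp = _read_table(out / f"spike_phases_{cid}.tsv")
            parts.append(sp[sp["band"] == "ripple"]["phase"].to_numpy())
        pooled[klass] = np.concatenate(parts) if parts else np.array([])

    comp_rows = []
    if pooled.get("BC", np.array([])).size >= 5 and pooled.get("Bistrat", np.array([])).size >= 5:
        f, p = watson_williams(pooled["BC"], pooled["Bistrat"])
        comp_rows.append(
            ("event_phase_BC_vs_Bistrat", "watson_williams", f, p,
             pooled["BC"].size, pooled["Bistrat"].size)
        )
    by_class = {k: g["rate_run"].dropna().to_numpy() for k, g in rate_df.groupby("cell_class")}
    by_class = {k: v for k, v in by_class.items() if v.size >= 2}
    if len(by_class) >= 2:
        f, p = group_compare(by_class, "anova")
        comp_rows.append(
            ("rate_run_across_classes", "anova", f, p,
             *([sum(v.size for v in by_class.values())] * 2))
        )
    comparisons = pd.DataFrame(
        comp_rows,
        columns=["comparison", "test", "statistic", "p", "n1", "n2"],
    )
    # pairwise p-values are reported unadjusted by default; Holm step-down
    # adjustment available behind a config flag
    if config.get("report", {}).get("holm", False) and len(comparisons):
        p = comparisons["p"].to_numpy()
        order = np.argsort(p)
        m = p.size
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        comparisons["p_holm"] = adj
    _write_table(out / "cohort_summary.tsv", summary, config)
    _write_table(out / "comparisons.tsv", comparisons, config)

    events = rio.load_events(out / "events.tsv")
    log_lines = [
        _header(config).strip(),
        f"cells: {', '.join(meta['cell_id'])}",
        f"classes: {', '.join(sorted(meta['cell_class'].unique()))}",
        f"n_events_detected: {len(events)}",
        f"behavior: {config.get('behavior', {})}",
        f"detection: {config.get('detection', {})}",
        f"phases: {config.get('phases', {})}",
        f"rates: {config.get('rates', {})}",
        f"corefreq: {config.get('corefreq', {})}",
        "notes: envelope power = squared envelope; envelope SD normalization includes event samples",
    ]
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return {"summary": summary, "comparisons": comparisons}


def run_pipeline(config) -> dict[str, pd.DataFrame]:
    """Run every stage in order; returns the report tables."""
    config = _load_config(config)
    stage_simulate(config)
    stage_detect(config)
    stage_phases(config)
    stage_rates(config)
    stage_corefreq(config)
    return stage_report(config)
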