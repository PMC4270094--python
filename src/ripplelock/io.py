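"""Reading and writing the pipeline's on-disk formats.

Continuous signals (LFP, speed) live in an HDF5 container with one dataset
per channel and a ``fs`` attribute; spikes and events are headered
tab-delimited text with times in seconds to 6 decimals; configuration and
ground truth are YAML.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .core import LFPRecording, OscillationEvent, SpeedTrace, SpikeTrain
from .synth import GroundTruth

__all__ = [
    "save_signals",
    "load_signals",
    "save_spikes",
    "load_spikes",
    "save_events",
    "load_events",
    "save_yaml",
    "load_yaml",
    "save_ground_truth",
    "load_ground_truth",
]


def save_signals(path, channels: dict[str, LFPRecording]) -> None:
    """Write named continuous channels to one HDF5 file."""
    with h5py.File(path, "w") as f:
        for name, tr in channels.items():
            ds = f.create_dataset(name, data=tr.data)
            ds.attrs["fs"] = tr.fs
            ds.attrs["kind"] = "speed" if isinstance(tr, SpeedTrace) else "lfp"


def load_signals(path) -> dict[str, LFPRecording]:
    out: dict[str, LFPRecording] = {}
    with h5py.File(path, "r") as f:
        for name, ds in f.items():
            cls = SpeedTrace if ds.attrs.get("kind") == "speed" else LFPRecording
            out[name] = cls(ds[...], float(ds.attrs["fs"]))
    return out


def save_spikes(path, spikes: SpikeTrain) -> None:
    with open(path, "w") as f:
        f.write(f"# cell_id={spikes.cell_id}\nspike_time_s\n")
        for t in spikes.times:
            f.write(f"{t:.6f}\n")


def load_spikes(path) -> SpikeTrain:
    cell_id = ""
    times = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if line.startswith("#"):
                if "cell_id=" in line:
                    cell_id = line.split("cell_id=", 1)[1]
            elif line and not line[0].isalpha():
                times.append(float(line))
    return SpikeTrain(np.asarray(times), cell_id)


_EVENT_COLS = ["start", "end", "peak_time", "peak_amplitude", "core_freq"]


def save_events(path, events: list[OscillationEvent]) -> None:
    df = pd.DataFrame([{c: getattr(e, c) for c in _EVENT_COLS} for e in events])
    if df.empty:
        df = pd.DataFrame(columns=_EVENT_COLS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def load_events(path) -> list[OscillationEvent]:
    df = pd.read_csv(path, sep="\t")
    return [OscillationEvent(**{c: float(row[c]) for c in _EVENT_COLS}) for _, row in df.iterrows()]


def save_yaml(path, payload: dict) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(payload, f, sort_keys=True)


def load_yaml(path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_ground_truth(path, gt: GroundTruth) -> None:
    save_yaml(path, gt.to_dict())


def load_ground_truth(path) -> GroundTruth:
    return GroundTruth.from_dict(load_yaml(path))
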