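"""Cell metadata, group comparisons, and phase-lag latency conversion.

The cell table mirrors the study design this package targets: a cohort of
juxtacellularly identified parvalbumin interneurons, each assigned to a
class (BC = basket cell, Bistrat = bistratified cell, AAC = axo-axonic
cell) and a morphological sub-class (C-/H-BC, C-/O-Bistrat, C-/E-AAC), with
immunomarker outcomes in a three-level vocabulary (+, -, n.t.).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .phase import watson_williams

__all__ = [
    "CellRecord",
    "SUB_CLASSES",
    "MARKER_VALUES",
    "make_cell_table",
    "load_cell_table",
    "phase_lag_to_ms",
    "group_compare",
]

SUB_CLASSES = ("C-BC", "H-BC", "C-Bistrat", "O-Bistrat", "C-AAC", "E-AAC")
MARKER_VALUES = ("+", "-", "n.t.")
_MARKER_COLS = ("parvalbumin", "somatostatin", "mGluR1a", "SATB1")


@dataclass(frozen=True)
class CellRecord:
    cell_id: str
    sub_class: str
    parvalbumin: str = "n.t."
    somatostatin: str = "n.t."
    mGluR1a: str = "n.t."
    SATB1: str = "n.t."
    bouton_targets: str = "n.t."
    ankyrinG: str = "n.t."
    EM: str = "n.t."

    @property
    def cell_class(self) -> str:
        return self.sub_class.split("-", 1)[1]


def _validate_table(df: pd.DataFrame, source: str) -> pd.DataFrame:
    required = ["cell_id", "sub_class", *(_MARKER_COLS)]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing columns {missing}")
    for i, row in df.iterrows():
        if row["sub_class"] not in SUB_CLASSES:
            raise ValueError(f"{source} row {i + 2}: unknown sub_class {row['sub_class']!r}")
        for col in _MARKER_COLS:
            if str(row[col]) not in MARKER_VALUES:
                raise ValueError(
                    f"{source} row {i + 2}: marker {col}={row[col]!r} not in {MARKER_VALUES}"
                )
    if df["cell_id"].duplicated().any():
        raise ValueError(f"{source}: duplicate cell ids")
    df = df.copy()
    df["cell_class"] = df["sub_class"].str.split("-", n=1).str[1]
    return df


def make_cell_table() -> pd.DataFrame:
    """The packaged 27-cell metadata table (validated)."""
    with resources.files("ripplelock.data").joinpath("cell_table.tsv").open() as f:
        df = pd.read_csv(f, sep="\t", dtype=str)
    return _validate_table(df, "packaged cell table")


def load_cell_table(path) -> list[CellRecord]:
    """Load and validate a cell metadata table; returns one record per row."""
    df = _validate_table(pd.read_csv(path, sep="\t", dtype=str), str(path))
    cols = [f.name for f in CellRecord.__dataclass_fields__.values()]  # type: ignore[attr-defined]
    return [
        CellRecord(**{c: str(row[c]) for c in cols if c in row.index}) for _, row in df.iterrows()
    ]


def phase_lag_to_ms(delta_deg: float, freq_hz: float, granularity: float | None = None) -> float:
    """Convert a phase lag (degrees) at an oscillation frequency to a latency.

    ``latency = delta/360 * 1000/freq`` ms, optionally rounded to the given
    granularity in ms (e.g. 1 for whole milliseconds, 10 for tens of ms).
    A 71 deg lag at 8 Hz theta is 25 ms; the same lag at a 140 Hz ripple is
    1.4 ms.
    """
    if freq_hz <= 0:
        raise ValueError("frequency must be positive")
    ms = (delta_deg / 360.0) * (1000.0 / freq_hz)
    if granularity is not None:
        if granularity <= 0:
            raise ValueError("granularity must be positive")
        ms = round(ms / granularity) * granularity
    return float(ms)


_LINEAR_FAMILIES = ("anova", "kruskal_wallis", "mann_whitney", "wilcoxon_signed_rank")


def group_compare(
    groups: dict[str, np.ndarray] | list,
    family: str,
    circular: bool = False,
) -> tuple[float, float]:
    """Named-family group comparison; returns (statistic, p).

    Circular data (phases in degrees) are only accepted by
    ``watson_williams``; passing them to a linear family — or linear data to
    the circular family — is rejected rather than silently mis-analyzed.
    """
    vals = list(groups.values()) if isinstance(groups, dict) else list(groups)
    vals = [np.asarray(v, dtype=float) for v in vals]
    if any(v.size < 2 for v in vals):
        raise ValueError("each group needs at least 2 values")
    if family == "watson_williams":
        if not circular:
            raise ValueError("watson_williams is for circular data; pass circular=True")
        return watson_williams(*vals)
    if circular:
        raise ValueError(f"circular data passed to linear family {family!r}")
    if family == "anova":
        res = spstats.f_oneway(*vals)
    elif family == "kruskal_wallis":
        res = spstats.kruskal(*vals)
    elif family == "mann_whitney":
        if len(vals) != 2:
            raise ValueError("mann_whitney compares exactly two groups")
        res = spstats.mannwhitneyu(*vals, alternative="two-sided")
    elif family == "wilcoxon_signed_rank":
        if len(vals) != 2 or vals[0].size != vals[1].size:
            raise ValueError("wilcoxon_signed_rank needs two paired groups")
        res = spstats.wilcoxon(*vals)
    else:
        raise ValueError(f"unknown family {family!r}")
    return float(res.statistic), float(res.pvalue)
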