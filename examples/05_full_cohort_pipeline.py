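"""Run the full pipeline on the bundled six-cell demo cohort.

Simulates a run (theta) + rest (ripples) session with two cells per
interneuron class — basket (BC), bistratified (Bistrat) and axo-axonic
(AAC), each pair split into contrasting sub-classes — then detects events,
computes per-cell phase locking and rates, and prints the cohort summary.
"""

import tempfile
from pathlib import Path

import pandas as pd

from ripplelock.pipeline import demo_config, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    tables = run_pipeline(demo_config(Path(tmp) / "demo", seed=1))

summary = tables["summary"].set_index("cell_class")
cols = ["rate_run_mean", "theta_phase_mean", "event_phase_mean",
        "rate_in_mean", "participation_mean", "doublet_fraction_mean"]
pd.set_option("display.width", 120)
pd.set_option("display.max_columns", None)
print(summary[cols].round(2))
print()
print(tables["comparisons"].round(4).to_string(index=False))
# Planted structure the report should recover: theta phases near 310 (BC),
# 0/360 (Bistrat) and 251 (AAC) deg; BC event phase (55 deg) earlier than
# Bistrat (126 deg) with a decisive Watson-Williams p; basket cells
# participating in every event.
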