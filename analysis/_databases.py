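"""Shared helper: the six study databases, generated once and cached on disk.

Raw simulated CSVs live under scratch/ (they are working data, not results);
every numbered analysis script regenerates them only when missing.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

import strokevalnet as sv

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "dbs"
RESULTS = ROOT / "results"

BASE_SEED = 42

PRESETS = (
    "claims_under65",
    "medicare_65plus",
    "medicaid_mixed",
    "ehr_large",
    "hospital_small",
    "no_inpatient_stroke",
)


def database_dir(preset: str) -> Path:
    return SCRATCH / preset


def get_databases() -> dict[str, tuple[sv.LongitudinalDatabase, pd.DataFrame]]:
    """Generate (or reload) all six databases with their ground truth."""
    out = {}
    for i, preset in enumerate(PRESETS):
        path = database_dir(preset)
        truth_file = path / "ground_truth.csv"
        if truth_file.is_file():
            db = sv.load_database(path, name=preset)
            truth = pd.read_csv(truth_file, parse_dates=["index_date"])
        else:
            profile = sv.make_profile(preset)
            db, truth = sv.generate_database(profile, seed=BASE_SEED + i)
            sv.save_database(db, path)
            truth.to_csv(truth_file, index=False, lineterminator="\n")
        out[preset] = (db, truth)
    return out
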