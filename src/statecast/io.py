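"""CSV serialization of cohorts.

Two files describe a cohort:

* a long-format monitored table with header
  ``individual_id,time,state,v01..vK`` where ``time`` is a 0-based integer
  grid index;
* a baseline table with header ``individual_id,sex,age,weight,height``.

The same dialect is accepted for user-supplied data directories.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InputError
from .synthetic import BaselineRecord, IndividualRecord

MONITORED_FILENAME = "cohort.csv"
BASELINE_FILENAME = "baselines.csv"


def variable_columns(k: int) -> list[str]:
    width = max(2, len(str(k)))
    return [f"v{j:0{width}d}" for j in range(1, k + 1)]


def cohort_to_frames(cohort: list[IndividualRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long monitored frame and baseline frame for a cohort."""
    if not cohort:
        cols = ["individual_id", "time", "state"]
        return (
            pd.DataFrame(columns=cols),
            pd.DataFrame(columns=["individual_id", "sex", "age", "weight", "height"]),
        )
    k = cohort[0].monitors.shape[1]
    vcols = variable_columns(k)
    parts = []
    base_rows = []
    for rec in cohort:
        frame = pd.DataFrame(rec.monitors, columns=vcols)
        frame.insert(0, "individual_id", rec.id)
        frame.insert(1, "time", np.arange(rec.t_n))
        frame.insert(2, "state", rec.states)
        parts.append(frame)
        base_rows.append(
            {
                "individual_id": rec.id,
                "sex": rec.baseline.sex,
                "age": rec.baseline.age,
                "weight": rec.baseline.weight,
                "height": rec.baseline.height,
            }
        )
    return pd.concat(parts, ignore_index=True), pd.DataFrame(base_rows)


def write_cohort(cohort: list[IndividualRecord], out_dir) -> tuple[Path, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    long_df, base_df = cohort_to_frames(cohort)
    monitored_path = out_dir / MONITORED_FILENAME
    baseline_path = out_dir / BASELINE_FILENAME
    long_df.to_csv(monitored_path, index=False)
    base_df.to_csv(baseline_path, index=False)
    return monitored_path, baseline_path


def read_cohort(data_dir) -> list[IndividualRecord]:
    """Read a cohort from ``cohort.csv`` + ``baselines.csv`` in a directory."""
    data_dir = Path(data_dir)
    long_df = pd.read_csv(data_dir / MONITORED_FILENAME)
    base_df = pd.read_csv(data_dir / BASELINE_FILENAME)
    return frames_to_cohort(long_df, base_df)


def frames_to_cohort(long_df: pd.DataFrame, base_df: pd.DataFrame) -> list[IndividualRecord]:
    required = {"individual_id", "time", "state"}
    if not required.issubset(long_df.columns):
        raise InputError(f"monitored table must contain columns {sorted(required)}")
    vcols = [c for c in long_df.columns if c not in required]
    if not vcols:
        raise InputError("monitored table contains no variable columns")
    baselines = base_df.set_index("individual_id")
    cohort = []
    for ident, group in long_df.groupby("individual_id", sort=True):
        group = group.sort_values("time")
        times = group["time"].to_numpy()
        if not np.array_equal(times, np.arange(times.size)):
            raise InputError(f"individual {ident}: time must be a 0-based contiguous grid")
        states = group["state"].to_numpy()
        if not np.all(np.isin(states, [0, 1])):
            raise InputError(f"individual {ident}: state must be binary")
        if ident not in baselines.index:
            raise InputError(f"individual {ident}: missing baseline row")
        b = baselines.loc[ident]
        cohort.append(
            IndividualRecord(
                id=str(ident),
                monitors=group[vcols].to_numpy(dtype=float),
                states=states.astype(np.int64),
                baseline=BaselineRecord(
                    sex=str(b["sex"]),
                    age=float(b["age"]),
                    weight=float(b["weight"]),
                    height=float(b["height"]),
                ),
            )
        )
    return cohort
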