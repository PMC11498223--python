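"""Long-format CSV schemas for trace cohorts and their truth sidecars.

Trace tables are tidy CSV, one row per cell per frame::

    cell_id, time_h, area, rb_raw, geminin_raw, hdhb_nuc, hdhb_cyt,
    bg_median[, birth_time_h, division_time_h]

The generator's ground truth travels in a separate sidecar CSV (one row per
cell; non-scalar entries JSON-encoded) so that processed data can never
silently depend on it.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic import CellTrace

__all__ = [
    "write_cohort_csv",
    "write_truth_csv",
    "read_trace_table",
    "read_truth_csv",
    "SchemaError",
]

REQUIRED_COLUMNS = (
    "cell_id",
    "time_h",
    "area",
    "rb_raw",
    "geminin_raw",
    "hdhb_nuc",
    "hdhb_cyt",
    "bg_median",
)

_CHANNEL_COLUMNS = {
    "rb": "rb_raw",
    "geminin": "geminin_raw",
    "hdhb_nuc": "hdhb_nuc",
    "hdhb_cyt": "hdhb_cyt",
}


class SchemaError(ValueError):
    """The trace table violates the expected schema."""


def cohort_to_frame(cohort: Sequence[CellTrace]) -> pd.DataFrame:
    frames = []
    for trace in cohort:
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": trace.cell_id,
                    "time_h": trace.times,
                    "area": trace.nuclear_area,
                    "rb_raw": trace.raw_intensity["rb"],
                    "geminin_raw": trace.raw_intensity["geminin"],
                    "hdhb_nuc": trace.raw_intensity["hdhb_nuc"],
                    "hdhb_cyt": trace.raw_intensity["hdhb_cyt"],
                    "bg_median": trace.background_median,
                    "birth_time_h": trace.birth_time if trace.birth_time is not None else np.nan,
                    "division_time_h": (
                        trace.division_time if trace.division_time is not None else np.nan
                    ),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def write_cohort_csv(cohort: Sequence[CellTrace], path: str | Path) -> None:
    cohort_to_frame(cohort).to_csv(path, index=False)


def write_truth_csv(cohort: Sequence[CellTrace], path: str | Path) -> None:
    """Sidecar with the generator's per-cell ground truth."""
    rows = []
    for trace in cohort:
        if trace.truth is None:
            continue
        row = {"cell_id": trace.cell_id}
        for key, val in trace.truth.items():
            row[key] = json.dumps(val) if isinstance(val, (list, dict, tuple)) else val
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_truth_csv(path: str | Path) -> dict[str, dict]:
    df = pd.read_csv(path)
    out: dict[str, dict] = {}
    for _, row in df.iterrows():
        truth = {}
        for key, val in row.items():
            if key == "cell_id":
                continue
            if isinstance(val, str) and val[:1] in "[{":
                val = json.loads(val)
            truth[key] = val
        out[str(row["cell_id"])] = truth
    return out


def read_trace_table(path: str | Path, truth_path: Optional[str | Path] = None) -> list[CellTrace]:
    """Parse and validate a long-format trace CSV.

    Rows may appear in any order; they are grouped by cell and sorted by
    time.  Violations (missing column, non-uniform grid, non-positive area)
    raise :class:`SchemaError` naming the offending column or cell.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trace table is missing required column(s): {', '.join(missing)}")
    truth_by_cell = read_truth_csv(truth_path) if truth_path else {}

    cohort = []
    for cell_id, group in df.groupby("cell_id", sort=True):
        group = group.sort_values("time_h")
        times = group["time_h"].to_numpy(dtype=float)
        dts = np.diff(times)
        if len(dts) and (np.any(dts <= 0) or np.ptp(dts) > 1e-9):
            raise SchemaError(f"cell {cell_id}: non-uniform or non-increasing time grid")
        area = group["area"].to_numpy(dtype=float)
        if np.any(area <= 0):
            raise SchemaError(f"cell {cell_id}: non-positive nuclear area")
        birth = group["birth_time_h"].iloc[0] if "birth_time_h" in group else np.nan
        division = group["division_time_h"].iloc[0] if "division_time_h" in group else np.nan
        cohort.append(
            CellTrace(
                cell_id=str(cell_id),
                times=times,
                nuclear_area=area,
                raw_intensity={
                    name: group[col].to_numpy(dtype=float)
                    for name, col in _CHANNEL_COLUMNS.items()
                },
                background_median=group["bg_median"].to_numpy(dtype=float),
                birth_time=None if pd.isna(birth) else float(birth),
                division_time=None if pd.isna(division) else float(division),
                truth=truth_by_cell.get(str(cell_id)),
            )
        )
    return cohort
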