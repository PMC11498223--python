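"""Background correction, concentration conversion, phase annotation and
trace alignment.

Conventions follow the standard live-imaging pipeline downstream of nuclear
segmentation: each object's integrated intensity is corrected by the image's
median background times its area, and concentration is the corrected
intensity divided by the nuclear volume proxy area^{3/2} (nuclear volume
scales with cell volume).  Cell-cycle phases come from a Geminin-type S-G2
reporter: frames with Geminin above threshold are S-G2; the maximal
Geminin-negative run from birth is G1, and qualifies as *early G1* only if
it lasts longer than 7 hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .synthetic import CellTrace

__all__ = [
    "ConcentrationTrace",
    "PhaseAnnotation",
    "concentration_trace",
    "cohort_geminin_threshold",
    "annotate_phases",
    "align_and_normalize",
    "fold_change",
]

#: early-G1 qualification rule: the Geminin-negative run must exceed this
EARLY_G1_MIN_HOURS = 7.0


@dataclass
class ConcentrationTrace:
    """Background-corrected concentration time series for one cell."""

    cell_id: str
    times: np.ndarray
    concentration: np.ndarray
    corrected_intensity: np.ndarray
    volume_proxy: np.ndarray
    floored_frames: int = 0  # frames where correction went negative


@dataclass
class PhaseAnnotation:
    """Labelled phase intervals for one cell (half-open [start, end))."""

    cell_id: str
    intervals: list[tuple[float, float, str]]
    geminin_threshold: float

    def interval(self, label: str) -> Optional[tuple[float, float]]:
        for start, end, lab in self.intervals:
            if lab == label:
                return (start, end)
        return None


def concentration_trace(trace: CellTrace, channel: str = "rb") -> ConcentrationTrace:
    """Convert a raw trace to concentration units.

    corrected = raw - background_median * area, floored at zero (with the
    number of floored frames recorded); concentration = corrected /
    area^{3/2}.

    Raises
    ------
    KeyError
        if the channel is missing.
    ValueError
        if the background is missing (no silent zero-background assumption).
    """
    if channel not in trace.raw_intensity:
        raise KeyError(f"cell {trace.cell_id}: channel {channel!r} not present")
    if trace.background_median is None or len(trace.background_median) != trace.n_frames:
        raise ValueError(f"cell {trace.cell_id}: background_median missing or wrong length")
    corrected = trace.raw_intensity[channel] - trace.background_median * trace.nuclear_area
    floored = int(np.sum(corrected < 0))
    corrected = np.maximum(corrected, 0.0)
    volume = trace.nuclear_area**1.5
    return ConcentrationTrace(
        cell_id=trace.cell_id,
        times=trace.times.copy(),
        concentration=corrected / volume,
        corrected_intensity=corrected,
        volume_proxy=volume,
        floored_frames=floored,
    )


def cohort_geminin_threshold(cohort: Iterable[CellTrace], factor: float = 3.0) -> float:
    """Default Geminin positivity threshold for a cohort.

    3x the median of the pooled lowest quartile of background-corrected
    Geminin values across all cells.  Pooling across the cohort keeps cells
    that are Geminin-positive (or -negative) for their entire trace
    classifiable, which a per-cell baseline cannot do.
    """
    corrected = []
    for trace in cohort:
        vals = trace.raw_intensity["geminin"] - trace.background_median * trace.nuclear_area
        corrected.append(np.maximum(vals, 0.0))
    pooled = np.concatenate(corrected)
    if not len(pooled):
        raise ValueError("empty cohort")
    q25 = np.percentile(pooled, 25)
    return factor * float(np.median(pooled[pooled <= q25]))


def annotate_phases(trace: CellTrace, geminin_threshold: float) -> PhaseAnnotation:
    """Phase annotation from the Geminin channel.

    Frames with background-corrected Geminin above ``geminin_threshold`` are
    S-G2; the maximal Geminin-negative run starting at birth is G1 and is
    additionally labelled early G1 iff it lasts longer than 7 hours.  Fully
    negative or fully positive traces are allowed and annotated as such.
    """
    if "geminin" not in trace.raw_intensity:
        raise KeyError(f"cell {trace.cell_id}: geminin channel not present")
    gem = trace.raw_intensity["geminin"] - trace.background_median * trace.nuclear_area
    positive = gem > geminin_threshold
    t = trace.times
    dt = t[1] - t[0] if len(t) > 1 else 0.0

    intervals: list[tuple[float, float, str]] = []
    if positive[0]:
        g1_end_idx = 0
    else:
        negative_run = np.flatnonzero(positive)
        g1_end_idx = int(negative_run[0]) if len(negative_run) else len(t)
        g1_start, g1_end = t[0], (t[g1_end_idx] if g1_end_idx < len(t) else t[-1] + dt)
        g1_length = g1_end - g1_start
        label = "earlyG1" if g1_length > EARLY_G1_MIN_HOURS else "G1"
        intervals.append((g1_start, g1_end, label))
    if g1_end_idx < len(t):
        intervals.append((t[g1_end_idx], t[-1] + dt, "SG2"))
    return PhaseAnnotation(
        cell_id=trace.cell_id, intervals=intervals, geminin_threshold=geminin_threshold
    )


def align_and_normalize(
    traces: Sequence[ConcentrationTrace],
    anchors: dict[str, float],
    dt: float = 1.0 / 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Align a group of concentration traces on per-cell anchor times.

    Each trace is re-indexed to time-since-anchor on the native sampling
    grid (no interpolation: frames are assigned to the nearest bin) and
    divided by the group's grand mean concentration.  Cells missing from
    ``anchors`` (or with a None anchor) are dropped; their count is
    returned.

    Returns
    -------
    aligned : DataFrame
        cells x time-bin matrix of normalised concentration.
    summary : DataFrame
        per-bin mean, standard deviation and cell count.
    n_dropped : int
    """
    rows = {}
    n_dropped = 0
    for trace in traces:
        anchor = anchors.get(trace.cell_id)
        if anchor is None:
            n_dropped += 1
            continue
        shifted = trace.times - anchor
        bins = np.round(shifted / dt).astype(int)
        rows[trace.cell_id] = pd.Series(trace.concentration, index=bins)
    if not rows:
        raise ValueError("empty group: no cell has an anchor time")
    aligned = pd.DataFrame(rows).T
    aligned.columns = aligned.columns * dt
    grand_mean = np.nanmean(aligned.to_numpy())
    if grand_mean <= 0:
        raise ValueError("group grand mean concentration is not positive")
    aligned = aligned / grand_mean
    summary = pd.DataFrame(
        {
            "mean": aligned.mean(axis=0, skipna=True),
            "sd": aligned.std(axis=0, skipna=True),
            "n": aligned.notna().sum(axis=0),
        }
    )
    return aligned, summary, n_dropped


def fold_change(treated_mean_conc: float, control_mean_conc: float) -> float:
    """Treatment-over-control concentration ratio (1 = no change)."""
    if control_mean_conc <= 0 or not math.isfinite(control_mean_conc):
        raise ValueError("control concentration must be positive and finite")
    return treated_mean_conc / control_mean_conc
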