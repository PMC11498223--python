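"""Cdk-activation detection, Cdk-low/high classification and the
concentration statistics of G1 progression.

The HDHB-type sensor translocates from nucleus to cytoplasm as Cdk activity
rises; the activation time is the inflection point of the cytoplasm-to-
nucleus intensity ratio, found here by fitting a four-parameter logistic.
Cells activating Cdk within 5 hours of birth are Cdk-high, all others
(including cells that never activate within the movie) are Cdk-low.

G1 exit is quantified two ways: the correlation between Rb concentration at
birth and G1 length, and a person-time hazard of the G1-S transition binned
by current concentration (each G1 cell-frame contributes its frame interval
of risk time to the bin of its concentration; transitions count as events
in the bin where they occur).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .traces import ConcentrationTrace, PhaseAnnotation

__all__ = [
    "CdkClassification",
    "TransitionRateCurve",
    "detect_cdk_activation",
    "classify_cdk",
    "birth_conc_vs_g1_length",
    "build_g1_risk_table",
    "transition_rate_vs_concentration",
]

CDK_HIGH_THRESHOLD_H = 5.0
MIN_FRAMES = 12


@dataclass
class CdkClassification:
    cell_id: str
    inflection_time: Optional[float]  # hours since birth; None if undetected
    cdk_class: str  # "low" | "high"
    diagnostics: dict


@dataclass
class TransitionRateCurve:
    bin_edges: np.ndarray
    events: np.ndarray
    risk_time: np.ndarray  # cell-hours at risk per bin
    rate: np.ndarray  # events per cell-hour
    association: float  # risk-time-weighted rank correlation (sign matters)
    p_value: float

    @property
    def bin_centres(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def _logistic(t, baseline, amplitude, midpoint, tau):
    return baseline + amplitude * special.expit((t - midpoint) / tau)


def detect_cdk_activation(
    times: np.ndarray, ratio: np.ndarray, amplitude_floor_snr: float = 3.0
) -> tuple[Optional[float], dict]:
    """Locate the sensor-ratio inflection by a 4-parameter logistic fit.

    Returns (inflection time, diagnostics).  The inflection is the fitted
    midpoint, accepted only when the fitted amplitude exceeds
    ``amplitude_floor_snr`` times the residual RMS and the midpoint lies
    inside the observed window; any fit failure yields (None, diagnostics)
    rather than an exception.
    """
    times = np.asarray(times, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if len(times) < MIN_FRAMES:
        return None, {"reason": "too_few_frames", "n_frames": len(times)}
    span = times[-1] - times[0]
    p0 = [
        float(np.min(ratio)),
        float(np.ptp(ratio)) or 1e-3,
        float(times[np.argmax(np.gradient(ratio))]),
        1.0,
    ]
    bounds = (
        [-np.inf, 0.0, times[0] - span, 1e-3],
        [np.inf, np.inf, times[-1] + span, span],
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                _logistic, times, ratio, p0=p0, bounds=bounds, maxfev=5000
            )
    except (RuntimeError, ValueError) as exc:
        return None, {"reason": "fit_failed", "error": str(exc)}
    baseline, amplitude, midpoint, tau = (float(v) for v in popt)
    resid_rms = float(np.sqrt(np.mean((ratio - _logistic(times, *popt)) ** 2)))
    diagnostics = {
        "amplitude": amplitude,
        "midpoint": midpoint,
        "tau": tau,
        "residual_rms": resid_rms,
    }
    if amplitude <= amplitude_floor_snr * max(resid_rms, 1e-12):
        diagnostics["reason"] = "amplitude_below_floor"
        return None, diagnostics
    if not times[0] <= midpoint <= times[-1]:
        diagnostics["reason"] = "midpoint_outside_window"
        return None, diagnostics
    return midpoint, diagnostics


def classify_cdk(
    inflection_since_birth: dict[str, Optional[float]],
    threshold: float = CDK_HIGH_THRESHOLD_H,
    diagnostics: Optional[dict[str, dict]] = None,
) -> list[CdkClassification]:
    """Label cells Cdk-high iff they activate within ``threshold`` hours of
    birth; undetected activation counts as Cdk-low ("activates later")."""
    out = []
    for cell_id, t_infl in inflection_since_birth.items():
        is_high = t_infl is not None and t_infl <= threshold
        out.append(
            CdkClassification(
                cell_id=cell_id,
                inflection_time=t_infl,
                cdk_class="high" if is_high else "low",
                diagnostics=(diagnostics or {}).get(cell_id, {}),
            )
        )
    return out


def birth_conc_vs_g1_length(
    birth_conc: Sequence[float], g1_length: Sequence[float]
) -> dict:
    """Pearson correlation (Spearman alongside) of birth concentration
    against G1 length for one Cdk class."""
    x = np.asarray(birth_conc, dtype=float)
    y = np.asarray(g1_length, dtype=float)
    if len(x) < 3:
        raise ValueError(f"need >= 3 cells, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance: correlation undefined")
    pearson = stats.pearsonr(x, y)
    spearman = stats.spearmanr(x, y)
    return {
        "r": float(pearson.statistic),
        "p": float(pearson.pvalue),
        "spearman_rho": float(spearman.statistic),
        "spearman_p": float(spearman.pvalue),
        "n": len(x),
    }


def build_g1_risk_table(
    conc_traces: Sequence[ConcentrationTrace],
    annotations: dict[str, PhaseAnnotation],
    dt: float = 1.0 / 3.0,
) -> pd.DataFrame:
    """Person-time table of G1 cell-frames.

    Every frame inside a cell's G1 (or early-G1) interval contributes
    ``dt`` hours of risk at its concentration; the last G1 frame of a cell
    whose trace continues into S-G2 carries the transition event.
    """
    records = []
    for trace in conc_traces:
        ann = annotations.get(trace.cell_id)
        if ann is None:
            continue
        g1 = ann.interval("earlyG1") or ann.interval("G1")
        if g1 is None:
            continue
        in_g1 = (trace.times >= g1[0]) & (trace.times < g1[1])
        idx = np.flatnonzero(in_g1)
        if not len(idx):
            continue
        transitions = ann.interval("SG2") is not None
        for j, i in enumerate(idx):
            records.append(
                {
                    "cell_id": trace.cell_id,
                    "conc": trace.concentration[i],
                    "risk_time": dt,
                    "event": int(transitions and j == len(idx) - 1),
                }
            )
    return pd.DataFrame.from_records(records, columns=["cell_id", "conc", "risk_time", "event"])


def _weighted_rank_association(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Risk-time-weighted Pearson correlation of ranks, with a t-test
    p-value at the effective sample size (sum w)^2 / sum w^2."""
    rx = stats.rankdata(x).astype(float)
    ry = stats.rankdata(y).astype(float)
    w = w / w.sum()
    mx, my = np.sum(w * rx), np.sum(w * ry)
    cov = np.sum(w * (rx - mx) * (ry - my))
    sx = math.sqrt(np.sum(w * (rx - mx) ** 2))
    sy = math.sqrt(np.sum(w * (ry - my) ** 2))
    if sx == 0 or sy == 0:
        return 0.0, 1.0
    r = cov / (sx * sy)
    n_eff = 1.0 / np.sum(w**2)
    if n_eff <= 2:
        return float(r), 1.0
    r_clip = min(max(r, -0.9999999), 0.9999999)
    tstat = r_clip * math.sqrt((n_eff - 2) / (1 - r_clip**2))
    p = 2.0 * stats.t.sf(abs(tstat), df=n_eff - 2)
    return float(r), float(p)


def transition_rate_vs_concentration(
    risk_table: pd.DataFrame, bin_edges: np.ndarray
) -> TransitionRateCurve:
    """Binned occurrence/exposure estimate of the G1-S transition hazard.

    rate(bin) = events(bin) / risk_time(bin); association is the weighted
    rank correlation between bin centre and rate over non-empty bins.
    """
    if risk_table.empty:
        raise ValueError("empty risk table")
    bin_edges = np.asarray(bin_edges, dtype=float)
    which = np.digitize(risk_table["conc"].to_numpy(), bin_edges) - 1
    inside = (which >= 0) & (which < len(bin_edges) - 1)
    if not inside.any():
        raise ValueError("all bins empty: no observations inside bin_edges")
    nbins = len(bin_edges) - 1
    events = np.bincount(
        which[inside], weights=risk_table["event"].to_numpy()[inside], minlength=nbins
    )
    risk = np.bincount(
        which[inside], weights=risk_table["risk_time"].to_numpy()[inside], minlength=nbins
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(risk > 0, events / np.where(risk > 0, risk, 1.0), np.nan)
    occupied = risk > 0
    centres = 0.5 * (bin_edges[:-1] + bin_edges[1:])
    if occupied.sum() >= 3:
        association, p = _weighted_rank_association(
            centres[occupied], rate[occupied], risk[occupied]
        )
    else:
        association, p = 0.0, 1.0
    return TransitionRateCurve(
        bin_edges=bin_edges,
        events=events,
        risk_time=risk,
        rate=rate,
        association=association,
        p_value=p,
    )
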