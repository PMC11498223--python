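"""Seeded synthetic single-cell trace cohorts.

Two experiment types are emulated, matching the statistical structure the
downstream estimators assume:

* **decay cohorts** — induction-withdrawal experiments: each cell carries an
  induced fluorescent reporter whose background-corrected intensity decays
  exponentially with a phase-dependent per-cell rate drawn from a two-piece
  log-normal half-life distribution; a Geminin-type S-G2 marker channel is
  on for S-G2 cells and off for early-G1 cells.
* **cycling cohorts** — asynchronously born cycling cells with growing
  nuclei, concentration dilution through G1 and recovery through S-G2-M,
  Geminin switching on at S entry, and an HDHB-type Cdk-activity ratio that
  rises as a logistic sigmoid around a drawn inflection time.

Measurement noise is multiplicative i.i.d. log-normal per frame (mean one,
coefficient of variation ``noise_cv``), plus an additive background of
``background_per_pixel * area`` on every intensity channel, mirroring how
integrated intensities inherit the image background.  Identical
(config, seed) pairs reproduce byte-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import GeneratorConfig

__all__ = ["CellTrace", "generate_decay_cohort", "generate_cycling_cohort"]

LN2 = math.log(2.0)

#: channel names present in every trace
CHANNELS = ("rb", "geminin", "hdhb_nuc", "hdhb_cyt")


@dataclass
class CellTrace:
    """One cell's sampled time series.

    ``raw_intensity`` maps channel name to per-frame integrated intensity;
    ``truth`` holds generator-only ground truth (present iff synthetic).
    """

    cell_id: str
    times: np.ndarray
    nuclear_area: np.ndarray
    raw_intensity: dict[str, np.ndarray]
    background_median: np.ndarray
    birth_time: Optional[float] = None
    division_time: Optional[float] = None
    truth: Optional[dict] = None

    def __post_init__(self) -> None:
        dts = np.diff(self.times)
        if len(dts) and (np.any(dts <= 0) or np.ptp(dts) > 1e-9):
            raise ValueError(f"cell {self.cell_id}: times must be a uniform increasing grid")
        if np.any(self.nuclear_area <= 0):
            raise ValueError(f"cell {self.cell_id}: nuclear areas must be positive")
        for name, vals in self.raw_intensity.items():
            if np.any(vals < 0):
                raise ValueError(f"cell {self.cell_id}: negative raw intensity in {name}")

    @property
    def n_frames(self) -> int:
        return len(self.times)


def _noise_factors(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(sigma * rng.standard_normal(n) - 0.5 * sigma * sigma)


def _areas(config: GeneratorConfig, rng: np.random.Generator, rel_times: np.ndarray) -> np.ndarray:
    area0 = config.area_initial * _noise_factors(rng, config.area_cv, 1)[0]
    return area0 * np.exp(config.area_growth_rate * rel_times)


def generate_decay_cohort(config: GeneratorConfig) -> list[CellTrace]:
    """Synthetic induction-withdrawal cohort.

    For every phase in ``config.halflife_specs`` (e.g. earlyG1 and SG2),
    ``config.n_cells`` cells are generated.  Each cell draws a true
    half-life from its phase's distribution; its reporter intensity is
    ``I0 * exp(-k t) * noise + background * area`` with ``k = ln2/t_half``.
    The Geminin channel is on for the whole movie iff the cell is in S-G2.
    """
    if not config.halflife_specs:
        raise ValueError("decay cohort requires halflife_specs")
    min_window = config.fit_start_delay + 10 * config.dt_sample
    if config.movie_length < min_window:
        raise ValueError(
            f"movie_length {config.movie_length} h too short for the fit window "
            f"(needs >= {min_window:.2f} h)"
        )
    rng = np.random.default_rng(config.seed)
    n_frames = int(round(config.movie_length / config.dt_sample)) + 1
    times = np.arange(n_frames) * config.dt_sample
    bg = np.full(n_frames, config.background_per_pixel)

    cohort: list[CellTrace] = []
    for phase in config.halflife_specs:
        spec = config.halflife_specs[phase]
        for i in range(config.n_cells):
            t_half = float(spec.sample(1, rng)[0])
            k = LN2 / t_half
            area = _areas(config, rng, times)
            signal = config.initial_intensity * np.exp(-k * times)
            rb_raw = signal * _noise_factors(rng, config.noise_cv, n_frames) + bg * area
            gem_on = phase in ("SG2", "SG2M")
            gem_signal = config.geminin_amplitude if gem_on else config.geminin_basal
            gem_raw = gem_signal * _noise_factors(rng, config.noise_cv, n_frames) + bg * area
            nuc = config.hdhb_nuc_level * _noise_factors(rng, config.noise_cv, n_frames)
            cyt = (
                config.cdk_ratio_baseline
                * config.hdhb_nuc_level
                * _noise_factors(rng, config.noise_cv, n_frames)
            )
            cohort.append(
                CellTrace(
                    cell_id=f"{config.condition_label}_{phase}_{i:04d}",
                    times=times.copy(),
                    nuclear_area=area,
                    raw_intensity={
                        "rb": rb_raw,
                        "geminin": gem_raw,
                        "hdhb_nuc": nuc,
                        "hdhb_cyt": cyt,
                    },
                    background_median=bg.copy(),
                    truth={
                        "phase": phase,
                        "k": k,
                        "t_half": t_half,
                        "phase_intervals": [(0.0, config.movie_length, phase)],
                    },
                )
            )
    return cohort


def generate_cycling_cohort(config: GeneratorConfig) -> list[CellTrace]:
    """Synthetic cycling cohort with staggered births.

    Ground-truth concentration declines exponentially through G1 at
    ``g1_dilution_rate`` (dilution: amount roughly constant while the
    nucleus grows) and recovers through S-G2-M back to the birth value at
    division.  G1 length is either drawn from the configured duration
    distribution — optionally scaled by (birth conc / median)**exponent to
    build in a positive concentration dependence — or generated by a
    constant-rate exit process (``g1_mode='hazard'``).
    """
    if "SG2M" not in config.phase_durations:
        raise ValueError("cycling cohort requires an SG2M phase-duration spec")
    if config.g1_mode == "duration" and "G1" not in config.phase_durations:
        raise ValueError("g1_mode='duration' requires a G1 phase-duration spec")
    if config.birth_concentration is None or config.cdk_inflection is None:
        raise ValueError("cycling cohort requires birth_concentration and cdk_inflection")
    rng = np.random.default_rng(config.seed)
    dt = config.dt_sample

    cohort: list[CellTrace] = []
    for i in range(config.n_cells):
        birth = float(rng.uniform(0.0, config.birth_stagger_fraction * config.movie_length))
        c0 = float(config.birth_concentration.sample(1, rng)[0])
        if config.g1_mode == "duration":
            scale = (c0 / config.birth_concentration.median) ** config.g1_conc_exponent
            g1_len = float(config.phase_durations["G1"].sample(1, rng)[0]) * scale
        else:
            g1_len = float(rng.exponential(1.0 / config.g1_hazard_rate))
        sg2m_len = float(config.phase_durations["SG2M"].sample(1, rng)[0])
        t_gs = birth + g1_len
        t_div = t_gs + sg2m_len
        division = t_div if t_div <= config.movie_length else None
        t_end = min(t_div, config.movie_length)
        n_frames = int(math.floor((t_end - birth) / dt)) + 1
        if n_frames < 2:
            continue
        times = birth + np.arange(n_frames) * dt
        rel = times - birth

        area = _areas(config, rng, rel)
        conc = np.where(
            times < t_gs,
            c0 * np.exp(-config.g1_dilution_rate * rel),
            c0
            * math.exp(-config.g1_dilution_rate * g1_len)
            * np.exp((config.g1_dilution_rate * g1_len / sg2m_len) * (times - t_gs)),
        )
        bg = np.full(n_frames, config.background_per_pixel)
        rb_signal = conc * area**1.5
        rb_raw = rb_signal * _noise_factors(rng, config.noise_cv, n_frames) + bg * area
        gem_signal = np.where(times >= t_gs, config.geminin_amplitude, config.geminin_basal)
        gem_raw = gem_signal * _noise_factors(rng, config.noise_cv, n_frames) + bg * area

        t_infl = birth + float(config.cdk_inflection.sample(1, rng)[0])
        ratio = config.cdk_ratio_baseline + config.cdk_ratio_amplitude / (
            1.0 + np.exp(-(times - t_infl) / config.cdk_sigmoid_tau)
        )
        nuc = config.hdhb_nuc_level * _noise_factors(rng, config.noise_cv, n_frames)
        cyt = ratio * config.hdhb_nuc_level * _noise_factors(rng, config.noise_cv, n_frames)

        cohort.append(
            CellTrace(
                cell_id=f"{config.condition_label}_{i:04d}",
                times=times,
                nuclear_area=area,
                raw_intensity={
                    "rb": rb_raw,
                    "geminin": gem_raw,
                    "hdhb_nuc": nuc,
                    "hdhb_cyt": cyt,
                },
                background_median=bg,
                birth_time=birth,
                division_time=division,
                truth={
                    "birth_concentration": c0,
                    "g1_length": g1_len,
                    "sg2m_length": sg2m_len,
                    "t_gs": t_gs,
                    "t_inflection": t_infl,
                    "dilution_rate": config.g1_dilution_rate,
                },
            )
        )
    return cohort
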