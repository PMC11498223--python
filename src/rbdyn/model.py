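"""Kinetic model of cell-cycle-dependent Rb concentration dynamics.

The model couples cell growth to Rb turnover:

    dM/dt  = gamma * M**delta                    (near-exponential growth)
    dRb/dt = alpha * M**delta - beta(t) * Rb     (synthesis ~ growth rate)

with concentration c = Rb / M.  The cell-cycle dependence enters through a
step change at the G1-S transition.  Two variants are implemented:

* ``degradation_step`` -- beta = beta0 in G1 and epsilon*beta0 (epsilon < 1)
  in S-G2-M, synthesis rate alpha constant.  This is the mechanism variant:
  Rb is degraded fast while un/hypo-phosphorylated in G1 and stabilised
  after Cdk phosphorylation.
* ``synthesis_step`` -- beta constant, alpha stepped up by a modest factor in
  S-G2-M.  The comparison variant used to show that a small synthesis
  up-regulation cannot reproduce the observed concentration swing.

The G1-S transition fires when the concentration crosses ``conc_threshold``
from above (dilution releases E2F); S-G2-M is a fixed-duration timer, after
which division halves both mass and Rb amount (concentration is continuous
across division).  Integration is explicit (Euler forward); from arbitrary
initial conditions the model is burnt in until it settles on its limit cycle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParams",
    "Trajectory",
    "simulate",
    "burn_in_to_limit_cycle",
    "simulate_decay_mode",
    "amount_dynamics_report",
    "concentration_amplitude",
    "compare_model_to_data",
]

G1 = "G1"
SG2M = "SG2M"

_VARIANTS = ("degradation_step", "synthesis_step")


@dataclass(frozen=True)
class ModelParams:
    """Parameter set for the growth-coupled Rb turnover model.

    Attributes
    ----------
    gamma : float
        Growth constant (1/h at unit mass); sets the mass doubling timescale.
    delta : float
        Growth-law exponent in [0, 1]; delta < 1 departs from pure
        exponential growth.
    alpha : float
        Effective synthesis rate; Rb production is alpha * M**delta.
    beta0 : float
        G1 degradation rate constant (1/h).
    epsilon : float
        Step factor in (0, 1]: S-G2-M degradation rate is epsilon * beta0
        in the degradation_step variant.
    conc_threshold : float
        Concentration below which the G1-S transition fires (downward
        crossing).
    t_sg2m : float
        Fixed S-G2-M duration (hours).
    dt : float
        Euler step (hours).
    variant : str
        "degradation_step" or "synthesis_step".
    synthesis_step_factor : float
        alpha multiplier in S-G2-M for the synthesis_step variant (>= 1).
    """

    gamma: float
    delta: float
    alpha: float
    beta0: float
    epsilon: float
    conc_threshold: float
    t_sg2m: float
    dt: float = 0.01
    burnin_max_cycles: int = 200
    burnin_tol: float = 1e-6
    variant: str = "degradation_step"
    synthesis_step_factor: float = 1.2
    max_g1_hours: float = 500.0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")
        if not 0 <= self.delta <= 1:
            raise ValueError("delta must lie in [0, 1]")
        for name in ("gamma", "alpha", "beta0", "conc_threshold", "t_sg2m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")
        if self.synthesis_step_factor < 1:
            raise ValueError("synthesis_step_factor must be >= 1")

    def rates(self, phase: str) -> tuple[float, float]:
        """Effective (alpha, beta) for a phase under the active variant."""
        if self.variant == "degradation_step":
            beta = self.beta0 if phase == G1 else self.epsilon * self.beta0
            return self.alpha, beta
        alpha = self.alpha if phase == G1 else self.alpha * self.synthesis_step_factor
        return alpha, self.beta0


@dataclass
class Trajectory:
    """A simulated path of the model."""

    times: np.ndarray
    mass: np.ndarray
    rb_amount: np.ndarray
    phase: np.ndarray  # array of "G1"/"SG2M" strings
    gs_times: list = field(default_factory=list)
    division_times: list = field(default_factory=list)
    converged: bool = False
    arrested: bool = False

    @property
    def concentration(self) -> np.ndarray:
        return self.rb_amount / self.mass


class _State:
    """Mutable integration state shared by the recording and burn-in loops."""

    __slots__ = ("t", "m", "rb", "phase", "phase_clock", "g1_clock")

    def __init__(self, m: float, rb: float):
        self.t = 0.0
        self.m = float(m)
        self.rb = float(rb)
        self.phase = G1
        self.phase_clock = 0.0  # time since entering the current phase
        self.g1_clock = 0.0

    @property
    def conc(self) -> float:
        return self.rb / self.m


def _step(params: ModelParams, s: _State) -> tuple[str, float] | None:
    """Advance the state by at most ``params.dt``, stopping at phase events.

    Euler forward on (M, Rb).  The G1-S threshold crossing is located within
    the step by linear interpolation and the S-G2-M timer expiry truncates
    the step exactly, so the integration grid re-aligns at every phase
    event: event times, and hence the cycle-to-cycle map used for burn-in,
    vary continuously instead of being quantised to the dt grid.  Division
    halves both M and Rb, keeping the concentration continuous.  Returns the
    event fired during the step, if any.
    """
    if s.phase == SG2M:
        h = min(params.dt, params.t_sg2m - s.phase_clock)
    else:
        h = params.dt
    alpha_eff, beta_eff = params.rates(s.phase)
    mdelta = s.m**params.delta
    m_new = s.m + h * params.gamma * mdelta
    rb_new = s.rb + h * (alpha_eff * mdelta - beta_eff * s.rb)

    if s.phase == G1:
        c_prev, c_new = s.rb / s.m, rb_new / m_new
        if c_prev > params.conc_threshold >= c_new:
            frac = (c_prev - params.conc_threshold) / (c_prev - c_new)
            s.m += frac * (m_new - s.m)
            s.rb += frac * (rb_new - s.rb)
            s.t += frac * h
            s.phase = SG2M
            s.phase_clock = 0.0
            return ("gs", s.t)
        s.m, s.rb = m_new, rb_new
        s.t += h
        s.phase_clock += h
        s.g1_clock += h
        return None

    s.m, s.rb = m_new, rb_new
    s.t += h
    s.phase_clock += h
    if s.phase_clock >= params.t_sg2m - 1e-12:
        s.m *= 0.5
        s.rb *= 0.5
        s.phase = G1
        s.phase_clock = 0.0
        s.g1_clock = 0.0
        return ("division", s.t)
    return None


def simulate(
    params: ModelParams,
    initial: tuple[float, float],
    n_cycles: int,
    record: bool = True,
) -> Trajectory:
    """Euler-forward integration over ``n_cycles`` divisions.

    Starts in G1 at ``initial = (M0, Rb0)``.  If the concentration never
    crosses the threshold within ``params.max_g1_hours`` the run is flagged
    arrested and returned as-is (no exception).
    """
    m0, rb0 = initial
    if m0 <= 0:
        raise ValueError("initial mass must be positive")
    if rb0 < 0:
        raise ValueError("initial Rb amount must be non-negative")

    s = _State(m0, rb0)
    times, masses, rbs, phases = [0.0], [s.m], [s.rb], [s.phase]
    gs_times: list[float] = []
    division_times: list[float] = []
    arrested = False
    cycles_done = 0

    while cycles_done < n_cycles and not arrested:
        event = _step(params, s)
        if event is not None:
            kind, when = event
            if kind == "gs":
                gs_times.append(when)
            else:
                division_times.append(when)
                cycles_done += 1
        if record:
            times.append(s.t)
            masses.append(s.m)
            rbs.append(s.rb)
            phases.append(s.phase)
        if s.phase == G1 and s.g1_clock >= params.max_g1_hours:
            arrested = True

    return Trajectory(
        times=np.asarray(times),
        mass=np.asarray(masses),
        rb_amount=np.asarray(rbs),
        phase=np.asarray(phases, dtype=object),
        gs_times=gs_times,
        division_times=division_times,
        arrested=arrested,
    )


def _one_cycle(params: ModelParams, s: _State) -> tuple[float, bool]:
    """Advance to the next division; return (cycle length, arrested)."""
    t_start = s.t
    while True:
        event = _step(params, s)
        if event is not None and event[0] == "division":
            return event[1] - t_start, False
        if s.phase == G1 and s.g1_clock >= params.max_g1_hours:
            return math.nan, True


def burn_in_to_limit_cycle(
    params: ModelParams, initial: tuple[float, float] | None = None
) -> Trajectory:
    """Iterate cycles until the limit cycle is reached; return one cycle.

    Convergence: relative change in (birth concentration, cycle length)
    between successive cycles < ``params.burnin_tol``.  The returned
    trajectory is the first post-convergence cycle (birth to division) with
    ``converged`` set; on non-convergence or arrest the flag stays False.
    """
    if initial is None:
        initial = (1.0, params.conc_threshold * 1.5)  # arbitrary start above threshold
    s = _State(*initial)
    prev = None
    converged = False
    for _ in range(params.burnin_max_cycles):
        cycle_len, arrested = _one_cycle(params, s)
        if arrested:
            traj = simulate(params, (s.m, s.rb), n_cycles=1)
            traj.arrested = True
            return traj
        birth_conc = s.conc
        if prev is not None:
            db = abs(birth_conc - prev[0]) / prev[0]
            dl = abs(cycle_len - prev[1]) / prev[1]
            if db < params.burnin_tol and dl < params.burnin_tol:
                converged = True
                break
        prev = (birth_conc, cycle_len)
    traj = simulate(params, (s.m, s.rb), n_cycles=1)
    traj.converged = converged and not traj.arrested
    return traj


def simulate_decay_mode(
    params: ModelParams, phase: str, duration: float, initial_rb: float = 1.0
) -> Trajectory:
    """Induction-withdrawal mode: synthesis off, phase pinned.

    With alpha forced to 0 and the phase held fixed, dRb/dt = -beta * Rb is
    linear with constant coefficient, so the amount series is written with
    its closed form Rb0 * exp(-beta t) (no discretisation bias in the rate
    the half-life estimator recovers); mass still grows by Euler forward.
    """
    if phase not in (G1, SG2M):
        raise ValueError(f"phase must be {G1!r} or {SG2M!r}")
    p = replace(params, alpha=0.0, conc_threshold=0.0)  # threshold can't fire
    dt = p.dt
    n = int(round(duration / dt))
    _, beta_eff = p.rates(phase)
    times = np.arange(n + 1) * dt
    rbs = float(initial_rb) * np.exp(-beta_eff * times)
    masses = np.empty(n + 1)
    m = 1.0
    for i in range(n + 1):
        masses[i] = m
        m = m + dt * p.gamma * m**p.delta
    return Trajectory(
        times=times,
        mass=masses,
        rb_amount=rbs,
        phase=np.full(n + 1, phase, dtype=object),
    )


def amount_dynamics_report(traj: Trajectory) -> dict:
    """Per-phase relative change of Rb amount on a limit-cycle trajectory.

    Returns the maximum relative deviation of the Rb amount from its value at
    G1 start over the first half of G1 (the "amount constancy" statistic),
    and the fold-accumulation of the amount over S-G2-M.
    """
    if not traj.gs_times:
        raise ValueError("trajectory has no G1-S transition")
    t = traj.times
    rb = traj.rb_amount
    t_gs = traj.gs_times[0]
    t0 = t[0]
    half_g1 = (t >= t0) & (t <= t0 + 0.5 * (t_gs - t0))
    rb0 = rb[half_g1][0]
    early_g1_rel_change = float(np.max(np.abs(rb[half_g1] - rb0)) / rb0)
    t_div = traj.division_times[0] if traj.division_times else t[-1]
    in_sg2m = (t >= t_gs) & (t <= t_div)
    # amount just before division (division halves rb at the boundary sample)
    sg2m_rb = rb[in_sg2m]
    sg2m_fold = float(np.max(sg2m_rb) / sg2m_rb[0])
    return {
        "early_g1_rel_change": early_g1_rel_change,
        "sg2m_fold_accumulation": sg2m_fold,
    }


def concentration_amplitude(traj: Trajectory) -> float:
    """(max - min)/mean of concentration over the trajectory."""
    c = traj.concentration
    return float((c.max() - c.min()) / c.mean())


def compare_model_to_data(
    traj: Trajectory,
    data_times: np.ndarray,
    data_mean: np.ndarray,
    anchor: str = "gs",
) -> float:
    """RMSE between mean-normalised model and data concentration traces.

    Both series are normalised to their own mean over the overlapping time
    range; the model is resampled onto the data grid, with time rebased so
    the G1-S transition (``anchor='gs'``) or trajectory start
    (``anchor='birth'``) sits at zero.
    """
    data_times = np.asarray(data_times, dtype=float)
    data_mean = np.asarray(data_mean, dtype=float)
    if anchor == "gs":
        if not traj.gs_times:
            raise ValueError("trajectory has no G1-S transition to anchor on")
        t0 = traj.gs_times[0]
    elif anchor == "birth":
        t0 = traj.times[0]
    else:
        raise ValueError("anchor must be 'gs' or 'birth'")
    model_t = traj.times - t0
    keep = (data_times >= model_t[0]) & (data_times <= model_t[-1])
    keep &= np.isfinite(data_mean)
    if not np.any(keep):
        raise ValueError("no temporal overlap between model and data")
    dtimes, dvals = data_times[keep], data_mean[keep]
    mvals = np.interp(dtimes, model_t, traj.concentration)
    mvals = mvals / mvals.mean()
    dvals = dvals / dvals.mean()
    return float(math.sqrt(np.mean((mvals - dvals) ** 2)))
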