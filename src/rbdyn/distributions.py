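"""Two-piece log-normal distributions for heterogeneous kinetic parameters.

Published single-cell half-life distributions are summarised as a median plus
an asymmetric central-75% range (12.5th-87.5th percentiles).  A plain
log-normal cannot match an asymmetric range in log-space, so cohorts are
parameterised with a *two-piece* log-normal: below the median, log-deviations
are normal with scale ``sigma_low``; above it, with scale ``sigma_high``.
Calibrating to (median, q_low, q_high) is then exact by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["DistributionSpec", "calibrate_two_piece_lognormal"]


@dataclass(frozen=True)
class DistributionSpec:
    """A two-piece log-normal, median-anchored.

    Parameters
    ----------
    median : float
        Median of the distribution (same units as the samples, e.g. hours).
    sigma_low, sigma_high : float
        Log-scale standard deviations of the lower and upper half.
    central_mass : float
        Fraction of probability mass in the calibrated central interval
        (default 0.75, i.e. the 12.5th-87.5th percentile band).
    """

    median: float
    sigma_low: float
    sigma_high: float
    central_mass: float = 0.75

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ValueError(f"median must be positive, got {self.median}")
        if self.sigma_low < 0 or self.sigma_high < 0:
            raise ValueError("sigma_low/sigma_high must be non-negative")
        if not 0 < self.central_mass < 1:
            raise ValueError("central_mass must lie in (0, 1)")

    def quantile(self, q):
        """Quantile function; lower piece for q < 0.5, upper for q >= 0.5."""
        q = np.asarray(q, dtype=float)
        if np.any((q <= 0) | (q >= 1)):
            raise ValueError("quantile levels must lie strictly in (0, 1)")
        z = stats.norm.ppf(q)
        sigma = np.where(q < 0.5, self.sigma_low, self.sigma_high)
        out = self.median * np.exp(sigma * z)
        return float(out) if out.ndim == 0 else out

    def central_interval(self) -> tuple[float, float]:
        """The (q_low, q_high) pair the spec was calibrated to."""
        tail = (1.0 - self.central_mass) / 2.0
        return self.quantile(tail), self.quantile(1.0 - tail)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` samples by inverse-transform of Uniform(0,1)."""
        u = rng.uniform(size=n)
        # clip away exact endpoints (probability zero, but be safe)
        u = np.clip(u, 1e-15, 1.0 - 1e-15)
        return np.asarray(self.quantile(u), dtype=float)

    def scaled(self, factor: float) -> "DistributionSpec":
        """Multiply the median by ``factor`` keeping the log-scale shape."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return DistributionSpec(
            self.median * factor, self.sigma_low, self.sigma_high, self.central_mass
        )


def calibrate_two_piece_lognormal(
    median: float, q_low: float, q_high: float, central_mass: float = 0.75
) -> DistributionSpec:
    """Build a :class:`DistributionSpec` matching three printed percentiles.

    ``q_low`` and ``q_high`` are the bounds of the central ``central_mass``
    interval, i.e. the (1-central_mass)/2 and 1-(1-central_mass)/2
    percentiles.  The calibration is exact::

        sigma_low  = ln(median / q_low)  / z
        sigma_high = ln(q_high / median) / z

    with z the standard-normal quantile at 1-(1-central_mass)/2.

    Raises
    ------
    ValueError
        if the quantiles are not strictly ordered 0 < q_low < median < q_high.
    """
    if not (0 < q_low < median < q_high):
        raise ValueError(
            "invalid calibration: need 0 < q_low < median < q_high, got "
            f"q_low={q_low}, median={median}, q_high={q_high}"
        )
    if not 0 < central_mass < 1:
        raise ValueError("central_mass must lie in (0, 1)")
    z = float(stats.norm.ppf(1.0 - (1.0 - central_mass) / 2.0))
    sigma_low = math.log(median / q_low) / z
    sigma_high = math.log(q_high / median) / z
    return DistributionSpec(float(median), sigma_low, sigma_high, float(central_mass))
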