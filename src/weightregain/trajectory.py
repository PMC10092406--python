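"""Scenario trajectories: weight difference over time and its BMI counterpart.

The lifetable consumes a piecewise-linear intervention-minus-control weight
difference D(t): the intervention population is ``d0`` kg lighter at
programme end and the advantage erodes linearly at ``rate`` kg/month until
it reaches zero (``linear_regain``), or persists forever (``no_regain``).
The weight difference becomes an age–sex BMI shift through ΔBMI = D/h²,
applied to the obese (BMI ≥ 30) adult subpopulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np

__all__ = ["Trajectory", "BmiShift", "make_trajectory", "weight_to_bmi_shift"]


@dataclass(frozen=True)
class Trajectory:
    """Piecewise-linear weight-difference function D(t), t in months since programme end."""

    d0: float  # programme-end difference, kg, < 0
    rate: float  # regain, kg/month, >= 0
    mode: Literal["linear_regain", "no_regain"] = "linear_regain"

    @property
    def t_zero_months(self) -> float | None:
        """Crossing time −d0/rate in months; None when never crossing."""
        if self.mode == "no_regain" or self.rate == 0.0:
            return None
        return -self.d0 / self.rate

    def weight_difference(self, t_months) -> np.ndarray:
        """D(t): min(d0 + rate·t, 0) for linear regain; constant d0 otherwise."""
        t = np.asarray(t_months, dtype=float)
        if self.mode == "no_regain":
            return np.broadcast_to(self.d0, t.shape).copy() if t.shape else np.float64(self.d0)
        return np.minimum(self.d0 + self.rate * t, 0.0)

    def midyear_samples(self, n_years: int, programme_end_month: float = 6.0) -> np.ndarray:
        """D sampled at mid-year months since baseline (6, 18, 30, ...).

        During the programme the difference ramps linearly from 0 at
        baseline to d0 at programme end; the regain clock starts there.
        """
        t_mid = 6.0 + 12.0 * np.arange(n_years, dtype=float)
        out = np.empty(n_years, dtype=float)
        before = t_mid < programme_end_month
        if programme_end_month > 0:
            out[before] = self.d0 * t_mid[before] / programme_end_month
        else:
            out[before] = self.d0
        out[~before] = self.weight_difference(t_mid[~before] - programme_end_month)
        return out


@dataclass(frozen=True)
class BmiShift:
    """Per-stratum BMI shift (kg/m², ≤ 0) for one model year."""

    delta_bmi: np.ndarray  # shaped like the heights mapping's strata
    year: int


def make_trajectory(
    d0: float,
    rate: float,
    mode: Literal["linear_regain", "no_regain"] = "linear_regain",
) -> Trajectory:
    """Validated trajectory constructor.

    ``d0`` must be negative (a weight-loss scenario) and ``rate``
    non-negative.  With ``rate == 0`` a linear-regain trajectory never
    crosses zero and ``t_zero_months`` is None.
    """
    if not d0 < 0:
        raise ValueError(f"d0 must be < 0 (weight-loss scenario); got {d0}")
    if rate < 0:
        raise ValueError(f"rate must be >= 0; got {rate}")
    if mode not in ("linear_regain", "no_regain"):
        raise ValueError(f"unknown mode {mode!r}")
    return Trajectory(d0=float(d0), rate=float(rate), mode=mode)


def weight_to_bmi_shift(
    trajectory: Trajectory,
    heights_m,
    t_months: float,
) -> np.ndarray:
    """BMI shift at time ``t_months`` since programme end: D(t)/h² per stratum.

    ``heights_m`` is an array (or mapping of stratum → metres); all heights
    must be positive.  The shift applies to the eligible (BMI ≥ 30)
    subpopulation only — that restriction is enforced where the shift meets
    the BMI distribution (in the population-impact-fraction integral).
    """
    if isinstance(heights_m, Mapping):
        keys = list(heights_m)
        h = np.asarray([heights_m[k] for k in keys], dtype=float)
    else:
        h = np.asarray(heights_m, dtype=float)
    if np.any(h <= 0):
        raise ValueError("heights must be positive (metres)")
    d = trajectory.weight_difference(t_months)
    return d / h**2
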