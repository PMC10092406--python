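"""Headline economics: threshold prices, ROI, and scaling by initial loss.

With a discounted per-person QALY gain Q and cost offset K (positive =
savings), the maximum per-person intervention price that remains
cost-effective at a willingness-to-pay threshold λ is the affine curve
C(λ) = λ·Q + K; C(0) is the cost-saving price.  Return on investment
monetizes the QALY (default £60,000) and is expressed as net return per £1
invested.  Per-person means per person *offered* the intervention (the
eligible BMI ≥ 30 population).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

from .lifetable import EpiInputs, ScenarioResult

__all__ = ["EconResult", "max_cost", "roi", "scale_by_initial_loss", "econ_from_scenarios"]

QALY_MONETIZED_VALUE = 60_000.0  # £/QALY for ROI, UK impact-assessment rate
NICE_LOWER, NICE_UPPER = 20_000.0, 30_000.0


def max_cost(q: float, k: float, wtp: float) -> float:
    """Maximum cost-effective per-person price C(λ) = λ·Q + K."""
    if wtp < 0:
        raise ValueError("willingness-to-pay threshold must be >= 0")
    return wtp * q + k


def roi(
    cost: float,
    q: float,
    k: float,
    qaly_value: float = QALY_MONETIZED_VALUE,
    gross: bool = False,
) -> float:
    """Return on investment at a per-person delivery cost.

    Net return per £1 invested: (v·Q + K − C)/C; ``gross=True`` instead
    reports (v·Q + K)/C.  Zero at the break-even price C = v·Q + K.
    """
    if cost <= 0:
        raise ValueError("intervention cost must be positive")
    value = qaly_value * q + k
    return value / cost if gross else (value - cost) / cost


@dataclass(frozen=True)
class EconResult:
    """Per-person economics of one scenario/perspective."""

    qaly_gain: float  # Q, QALYs per person offered
    cost_offset: float  # K, £ per person offered (positive = savings)
    perspective: Literal["health", "health_social"]
    n_offered: float

    def max_cost(self, wtp: float) -> float:
        return max_cost(self.qaly_gain, self.cost_offset, wtp)

    def curve(self, wtps: Sequence[float]) -> dict[float, float]:
        return {float(w): self.max_cost(w) for w in wtps}

    def roi(self, cost: float, qaly_value: float = QALY_MONETIZED_VALUE,
            gross: bool = False) -> float:
        return roi(cost, self.qaly_gain, self.cost_offset, qaly_value, gross)


def econ_from_scenarios(
    ref: ScenarioResult,
    intervention: ScenarioResult,
    epi: EpiInputs,
    perspective: Literal["health", "health_social"] = "health",
) -> EconResult:
    """Per-person Q and K from a reference/intervention scenario pair."""
    n = epi.eligible_population()
    if n <= 0:
        raise ValueError("no eligible population (BMI >= threshold)")
    q = (intervention.qalys - ref.qalys) / n
    k = (ref.total_costs(perspective) - intervention.total_costs(perspective)) / n
    return EconResult(qaly_gain=q, cost_offset=k, perspective=perspective, n_offered=n)


def scale_by_initial_loss(base: EconResult, w_new: float, w_base: float) -> EconResult:
    """Rescale Q and K for a different programme-end weight loss.

    Assumes health benefits (and hence cost offsets) scale linearly with the
    initial weight difference: both Q and K are multiplied by
    ``w_new / w_base`` and the price curve follows.
    """
    if w_base <= 0:
        raise ValueError("w_base must be positive")
    f = w_new / w_base
    return EconResult(
        qaly_gain=base.qaly_gain * f,
        cost_offset=base.cost_offset * f,
        perspective=base.perspective,
        n_offered=base.n_offered,
    )
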