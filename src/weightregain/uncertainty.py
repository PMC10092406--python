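"""Monte Carlo uncertainty propagation and tornado decomposition.

Input uncertainty is organized in *groups* (weight loss at programme end,
relative risks, unit costs, utilities), each with its own RNG stream split
from the master seed so that adding a group never perturbs another group's
draws.  Distribution families follow health-economic convention: lognormal
for relative risks, unit costs and the magnitude of programme-end weight
loss; normal for utility decrements; the regain *rate* carries no
uncertainty.  Intervals are percentile-based (2.5/97.5) because the
economic outputs are heavily right-skewed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .economics import econ_from_scenarios
from .lifetable import EpiInputs, _simulate, run_lifetable
from .trajectory import make_trajectory

__all__ = [
    "Quantity",
    "UncertaintySpec",
    "MCResult",
    "lognormal_from_mean_ci",
    "default_uncertainty_spec",
    "make_pipeline",
    "run_mc",
    "tornado",
]

_Z95 = 1.959963984540054

Family = Literal["lognormal", "normal", "fixed"]


def lognormal_from_mean_ci(mean: float, lo: float, hi: float) -> tuple[float, float]:
    """(μ, σ) of a lognormal with the given mean and 95% log-symmetric width.

    σ = (ln hi − ln lo)/(2·1.96); μ is then chosen so the distribution's
    *mean* (not median) equals ``mean``: μ = ln(mean) − σ²/2.  The (lo, hi)
    pair fixes the spread; the median √(lo·hi) need not equal the mean.
    """
    if not (0 < lo <= mean <= hi):
        raise ValueError(f"need 0 < lo <= mean <= hi; got ({lo}, {mean}, {hi})")
    sigma = (np.log(hi) - np.log(lo)) / (2 * _Z95)
    mu = np.log(mean) - sigma**2 / 2.0
    return float(mu), float(sigma)


@dataclass(frozen=True)
class Quantity:
    """One uncertain scalar: family, parameters, and validity bounds.

    ``params`` is (μ, σ) for lognormal, (mean, sd) for normal, (value,) for
    fixed.  Draws outside (lower, upper) are redrawn.
    """

    name: str
    family: Family
    params: tuple[float, ...]
    lower: float = -np.inf
    upper: float = np.inf

    @property
    def central(self) -> float:
        if self.family == "lognormal":
            mu, sigma = self.params
            return float(np.exp(mu + sigma**2 / 2.0))
        return float(self.params[0])

    def percentile(self, p: float) -> float:
        from scipy import stats

        if self.family == "fixed":
            return self.central
        if self.family == "lognormal":
            mu, sigma = self.params
            v = float(np.exp(mu + sigma * stats.norm.ppf(p)))
        else:
            mean, sd = self.params
            v = float(mean + sd * stats.norm.ppf(p))
        return float(np.clip(v, self.lower, self.upper))

    def draw(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, int]:
        """n valid draws plus the number of redraws needed."""
        if self.family == "fixed":
            return np.full(n, self.params[0]), 0
        redraws = 0
        if self.family == "lognormal":
            mu, sigma = self.params
            x = rng.lognormal(mu, sigma, size=n) if sigma > 0 else np.full(n, np.exp(mu))
        else:
            mean, sd = self.params
            x = rng.normal(mean, sd, size=n)
        bad = (x < self.lower) | (x > self.upper)
        while bad.any():
            redraws += int(bad.sum())
            if self.family == "lognormal":
                x[bad] = rng.lognormal(*self.params, size=int(bad.sum()))
            else:
                x[bad] = rng.normal(*self.params, size=int(bad.sum()))
            bad = (x < self.lower) | (x > self.upper)
            if redraws > 1000 * n:
                raise RuntimeError(f"quantity {self.name!r}: bounds reject nearly all draws")
        return x, redraws


@dataclass
class UncertaintySpec:
    """Uncertain input groups for the Monte Carlo layer."""

    groups: dict[str, list[Quantity]] = field(default_factory=dict)
    n_iterations: int = 5000
    seed: int = 0

    def central_draws(self) -> dict[str, dict[str, float]]:
        return {g: {q.name: q.central for q in qs} for g, qs in self.groups.items()}


def _group_rng(seed: int, group: str) -> np.random.Generator:
    # stable per-group stream: mixing the group name by CRC keeps streams
    # independent of how many other groups exist
    return np.random.default_rng(np.random.SeedSequence((seed, zlib.crc32(group.encode()))))


@dataclass
class MCResult:
    central: dict[str, float]
    lo: dict[str, float]
    hi: dict[str, float]
    draws: dict[str, np.ndarray] | None
    n_iterations: int
    n_redraws: int


def run_mc(
    pipeline: Callable[[dict[str, dict[str, float]]], dict[str, float]],
    spec: UncertaintySpec,
    save_draws: bool = True,
) -> MCResult:
    """Propagate input uncertainty through a deterministic pipeline.

    Runs ``spec.n_iterations`` end-to-end evaluations, one per joint draw,
    and reports percentile 95% uncertainty intervals around the central
    (all-inputs-at-central) estimate.  Identical seeds give bitwise
    identical results; invalid draws are redrawn and counted.
    """
    n = spec.n_iterations
    samples: dict[str, dict[str, np.ndarray]] = {}
    n_redraws = 0
    for gname in sorted(spec.groups):
        rng = _group_rng(spec.seed, gname)
        samples[gname] = {}
        for q in spec.groups[gname]:
            x, r = q.draw(rng, n)
            samples[gname][q.name] = x
            n_redraws += r

    outputs: dict[str, np.ndarray] | None = None
    for i in range(n):
        draw = {g: {k: float(v[i]) for k, v in qs.items()} for g, qs in samples.items()}
        out = pipeline(draw)
        if outputs is None:
            outputs = {k: np.empty(n) for k in out}
        for k, v in out.items():
            outputs[k][i] = v
    assert outputs is not None

    central = pipeline(spec.central_draws())
    lo = {k: float(np.percentile(v, 2.5)) for k, v in outputs.items()}
    hi = {k: float(np.percentile(v, 97.5)) for k, v in outputs.items()}
    return MCResult(
        central={k: float(v) for k, v in central.items()},
        lo=lo,
        hi=hi,
        draws=outputs if save_draws else None,
        n_iterations=n,
        n_redraws=n_redraws,
    )


def tornado(
    pipeline: Callable[[dict[str, dict[str, float]]], dict[str, float]],
    spec: UncertaintySpec,
    output: str,
) -> list[dict]:
    """One-way uncertainty decomposition of ``output``.

    Each group in turn is set to its 2.5th then 97.5th percentile (all
    quantities of the group moved together, all other groups at central
    values); the spread |high − low| ranks the groups.
    """
    if len(spec.groups) < 2:
        raise ValueError("tornado needs at least 2 uncertain input groups")
    central = spec.central_draws()
    rows = []
    for gname in sorted(spec.groups):
        vals = {}
        for p, tag in ((0.025, "low"), (0.975, "high")):
            draw = {g: dict(qs) for g, qs in central.items()}
            draw[gname] = {q.name: q.percentile(p) for q in spec.groups[gname]}
            vals[tag] = pipeline(draw)[output]
        rows.append(
            {
                "group": gname,
                "low": vals["low"],
                "high": vals["high"],
                "spread": abs(vals["high"] - vals["low"]),
            }
        )
    rows.sort(key=lambda r: -r["spread"])
    return rows


# ---------------------------------------------------------------------------
# Default spec + pipeline for the weight-regain scenario
# ---------------------------------------------------------------------------


def default_uncertainty_spec(
    epi: EpiInputs,
    d0: float,
    n_iterations: int = 5000,
    seed: int = 0,
) -> UncertaintySpec:
    """Uncertainty groups for the regain cost-effectiveness pipeline.

    Groups: ``weight_loss`` (|d0| lognormal, 95% interval from
    ``epi.d0_ci``), ``relative_risks`` (lognormal per disease, floored at
    1), ``unit_costs`` (lognormal per cost), ``utilities`` (normal
    decrements clipped to [0, 1]).  Missing CIs fall back to ×/÷2 for
    costs, a (1+(rr−1)/2, 1+2(rr−1)) band for RRs, and a 10%-of-value SD
    for utility decrements.  The regain rate is deliberately not a group.
    """
    mag = abs(d0)
    lo, hi = epi.d0_ci if epi.d0_ci else (mag / 2.0, mag * 2.0)
    groups: dict[str, list[Quantity]] = {
        "weight_loss": [
            Quantity("d0_kg", "lognormal", lognormal_from_mean_ci(mag, lo, hi), lower=1e-6)
        ]
    }
    rrs, costs, utils = [], [], []
    for d in epi.diseases:
        rr_ci = d.rr_ci or (1.0 + (d.rr_per_bmi_unit - 1.0) / 2.0,
                            1.0 + (d.rr_per_bmi_unit - 1.0) * 2.0)
        rrs.append(
            Quantity(f"rr_{d.name}", "lognormal",
                     lognormal_from_mean_ci(d.rr_per_bmi_unit, *rr_ci), lower=1.0)
        )
        cost_ci = d.annual_cost_ci or (d.annual_cost / 2.0, d.annual_cost * 2.0)
        costs.append(
            Quantity(f"cost_{d.name}", "lognormal",
                     lognormal_from_mean_ci(d.annual_cost, *cost_ci), lower=0.0)
        )
        sd = d.utility_decrement_sd
        if sd is None:
            sd = 0.1 * d.utility_decrement
        utils.append(
            Quantity(f"utility_decrement_{d.name}", "normal",
                     (d.utility_decrement, sd), lower=0.0, upper=1.0)
        )
    if epi.other_cause_cost > 0:
        ci = epi.other_cause_cost_ci or (epi.other_cause_cost / 2.0, epi.other_cause_cost * 2.0)
        costs.append(
            Quantity("other_cause_cost", "lognormal",
                     lognormal_from_mean_ci(epi.other_cause_cost, *ci), lower=0.0)
        )
    if epi.social_care_cost > 0:
        ci = epi.social_care_cost_ci or (epi.social_care_cost / 2.0, epi.social_care_cost * 2.0)
        costs.append(
            Quantity("social_care_cost", "lognormal",
                     lognormal_from_mean_ci(epi.social_care_cost, *ci), lower=0.0)
        )
    groups["relative_risks"] = rrs
    groups["unit_costs"] = costs
    groups["utilities"] = utils
    return UncertaintySpec(groups=groups, n_iterations=n_iterations, seed=seed)


def make_pipeline(
    epi: EpiInputs,
    rate_kg_per_month: float,
    mode: str = "linear_regain",
    perspective: str = "health",
    wtps: Sequence[float] = (0.0, 20_000.0, 30_000.0),
    programme_end_month: float = 6.0,
):
    """Deterministic draw → economics pipeline for :func:`run_mc`.

    A draw overrides |d0|, relative risks, unit costs, and utility
    decrements; the regain rate stays fixed and the trajectory's crossing
    time is re-derived per draw.  The reference scenario's state simulation
    does not depend on any drawn quantity and is computed once up front.
    Output keys: ``Q``, ``K``, and ``C_<λ>`` for each threshold.
    """
    epi.validate()
    ref_traces = _simulate(epi, None)
    masses = epi.bmi_masses()  # draw-independent; share across iterations
    from dataclasses import replace as _rep

    def pipeline(draw: dict[str, dict[str, float]]) -> dict[str, float]:
        wl = draw.get("weight_loss", {})
        d0 = -abs(wl.get("d0_kg", 1.0)) if wl else None
        rr = draw.get("relative_risks", {})
        uc = draw.get("unit_costs", {})
        ut = draw.get("utilities", {})
        diseases = [
            _rep(
                d,
                rr_per_bmi_unit=rr.get(f"rr_{d.name}", d.rr_per_bmi_unit),
                annual_cost=uc.get(f"cost_{d.name}", d.annual_cost),
                utility_decrement=ut.get(f"utility_decrement_{d.name}", d.utility_decrement),
            )
            for d in epi.diseases
        ]
        epi_i = _rep(
            epi,
            diseases=diseases,
            other_cause_cost=uc.get("other_cause_cost", epi.other_cause_cost),
            social_care_cost=uc.get("social_care_cost", epi.social_care_cost),
        )
        epi_i.__dict__["_bmi_masses_cache"] = masses
        traj = make_trajectory(d0 if d0 is not None else -1e-9, rate_kg_per_month, mode)
        ref, inter = run_lifetable(
            epi_i, traj, perspective, programme_end_month,
            keep_traces=False, _ref_traces=ref_traces,
        )
        econ = econ_from_scenarios(ref, inter, epi_i, perspective)
        out = {"Q": econ.qaly_gain, "K": econ.cost_offset}
        for w in wtps:
            out[f"C_{int(w)}"] = econ.max_cost(w)
        return out

    return pipeline
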