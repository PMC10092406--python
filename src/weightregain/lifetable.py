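"""Proportional multi-state lifetable with BMI-mediated disease risk.

Two populations — a reference and one whose obese (BMI ≥ 30) adults carry
an intervention weight-difference trajectory — age in annual cycles from a
baseline year until age 100.  Each disease runs a three-state
susceptible/case/dead difference equation whose incidence the intervention
perturbs through a population impact fraction (PIF) computed on the
stratum's continuous BMI distribution.  Disease-specific mortality
differences feed back into all-cause mortality; person-years, utilities,
and health/social-care costs accumulate with discounting to the baseline
year.

Diseases are treated as independent (no diabetes→cardiovascular risk
coupling).  Every cohort's BMI distribution and baseline epidemiology are
held at their baseline-year values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy import stats

from .errors import IntegrityError, StabilityError
from .trajectory import Trajectory

__all__ = [
    "DiseaseSpec",
    "EpiInputs",
    "ScenarioResult",
    "pif",
    "lognormal_bmi_masses",
    "run_disease",
    "run_lifetable",
    "discount",
]

AGE_MIN, AGE_MAX = 18, 100
SEXES = ("female", "male")

#: BMI evaluation grid (kg/m²): cell centres of [10, 60] at 0.1 resolution.
BMI_GRID_EDGES = np.round(np.arange(10.0, 60.0 + 0.05, 0.1), 10)
BMI_GRID = 0.5 * (BMI_GRID_EDGES[:-1] + BMI_GRID_EDGES[1:])


@dataclass
class DiseaseSpec:
    """One chronic disease in the lifetable.

    ``incidence`` and ``case_fatality`` are annual rates per susceptible /
    prevalent person, shaped (sex, age).  ``rr_per_bmi_unit`` is the
    relative risk per kg/m² above the reference BMI.  Optional ``*_ci`` /
    ``*_sd`` fields carry 95% uncertainty used by the Monte Carlo layer.
    """

    name: str
    incidence: np.ndarray
    case_fatality: np.ndarray
    rr_per_bmi_unit: float
    utility_decrement: float
    annual_cost: float
    rr_ci: tuple[float, float] | None = None
    annual_cost_ci: tuple[float, float] | None = None
    utility_decrement_sd: float | None = None


@dataclass
class EpiInputs:
    """Baseline-year population, epidemiology and unit costs by sex × age.

    All (sex, age) arrays are shaped ``(2, 83)`` for ages 18–100; BMI is
    lognormal per stratum (``ln BMI ~ N(ln median, dispersion²)``).
    """

    population: np.ndarray
    mortality: np.ndarray  # annual all-cause death probability
    bmi_median: np.ndarray
    bmi_dispersion: np.ndarray  # sigma of ln BMI
    height_m: np.ndarray
    utility: np.ndarray  # baseline utility in [0, 1]
    diseases: list[DiseaseSpec] = field(default_factory=list)
    other_cause_cost: float = 0.0
    social_care_cost: float = 0.0
    social_care_age: int = 85
    other_cause_cost_ci: tuple[float, float] | None = None
    social_care_cost_ci: tuple[float, float] | None = None
    discount_rate: float = 0.035
    baseline_year: int = 2017
    b_ref: float = 21.0
    eligible_bmi: float = 30.0
    d0_ci: tuple[float, float] | None = None  # 95% CI of |d0| for the MC layer

    @property
    def ages(self) -> np.ndarray:
        return np.arange(AGE_MIN, AGE_MAX + 1)

    def validate(self) -> None:
        shape = (len(SEXES), AGE_MAX - AGE_MIN + 1)
        for name in ("population", "mortality", "bmi_median", "bmi_dispersion",
                     "height_m", "utility"):
            arr = getattr(self, name)
            if np.asarray(arr).shape != shape:
                raise IntegrityError(f"{name} must have shape {shape}")
        if np.any(self.population < 0):
            raise IntegrityError("population counts must be >= 0")
        if np.any((self.mortality < 0) | (self.mortality >= 1)):
            raise IntegrityError("annual mortality probabilities must lie in [0, 1)")
        if np.any((self.utility < 0) | (self.utility > 1)):
            raise IntegrityError("utilities must lie in [0, 1]")
        if np.any(self.height_m <= 0):
            raise IntegrityError("heights must be positive")
        for d in self.diseases:
            if np.any(d.incidence < 0) or np.any(d.case_fatality < 0):
                raise IntegrityError(f"disease {d.name!r}: rates must be >= 0")
            if d.rr_per_bmi_unit < 1:
                raise IntegrityError(f"disease {d.name!r}: rr_per_bmi_unit must be >= 1")
            if not 0 <= d.utility_decrement <= 1:
                raise IntegrityError(f"disease {d.name!r}: utility decrement outside [0, 1]")

    # -- BMI machinery ------------------------------------------------------

    def bmi_masses(self) -> np.ndarray:
        """Per-stratum probability mass on the BMI grid, shape (2, 83, G).

        Cached on the instance; invalidated by :meth:`clear_cache` if the
        BMI arrays are mutated in place.
        """
        cached = self.__dict__.get("_bmi_masses_cache")
        if cached is None:
            cached = lognormal_bmi_masses(self.bmi_median, self.bmi_dispersion)
            self.__dict__["_bmi_masses_cache"] = cached
        return cached

    def clear_cache(self) -> None:
        self.__dict__.pop("_bmi_masses_cache", None)

    def prob_eligible(self) -> np.ndarray:
        """P(BMI ≥ eligibility threshold) per stratum from the grid masses."""
        masses = self.bmi_masses()
        return masses[..., BMI_GRID >= self.eligible_bmi].sum(axis=-1)

    def eligible_population(self) -> float:
        """Number of adults offered the intervention (BMI ≥ 30)."""
        return float(np.sum(self.population * self.prob_eligible()))

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        def arr(a):
            return np.asarray(a).tolist()

        return {
            "baseline_year": self.baseline_year,
            "discount_rate": self.discount_rate,
            "b_ref": self.b_ref,
            "eligible_bmi": self.eligible_bmi,
            "population": arr(self.population),
            "mortality": arr(self.mortality),
            "bmi_median": arr(self.bmi_median),
            "bmi_dispersion": arr(self.bmi_dispersion),
            "height_m": arr(self.height_m),
            "utility": arr(self.utility),
            "other_cause_cost": self.other_cause_cost,
            "social_care_cost": self.social_care_cost,
            "social_care_age": self.social_care_age,
            "other_cause_cost_ci": list(self.other_cause_cost_ci) if self.other_cause_cost_ci else None,
            "social_care_cost_ci": list(self.social_care_cost_ci) if self.social_care_cost_ci else None,
            "d0_ci": list(self.d0_ci) if self.d0_ci else None,
            "diseases": [
                {
                    "name": d.name,
                    "incidence": arr(d.incidence),
                    "case_fatality": arr(d.case_fatality),
                    "rr_per_bmi_unit": d.rr_per_bmi_unit,
                    "utility_decrement": d.utility_decrement,
                    "annual_cost": d.annual_cost,
                    "rr_ci": list(d.rr_ci) if d.rr_ci else None,
                    "annual_cost_ci": list(d.annual_cost_ci) if d.annual_cost_ci else None,
                    "utility_decrement_sd": d.utility_decrement_sd,
                }
                for d in self.diseases
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EpiInputs":
        diseases = [
            DiseaseSpec(
                name=x["name"],
                incidence=np.asarray(x["incidence"], dtype=float),
                case_fatality=np.asarray(x["case_fatality"], dtype=float),
                rr_per_bmi_unit=float(x["rr_per_bmi_unit"]),
                utility_decrement=float(x["utility_decrement"]),
                annual_cost=float(x["annual_cost"]),
                rr_ci=tuple(x["rr_ci"]) if x.get("rr_ci") else None,
                annual_cost_ci=tuple(x["annual_cost_ci"]) if x.get("annual_cost_ci") else None,
                utility_decrement_sd=x.get("utility_decrement_sd"),
            )
            for x in d.get("diseases", [])
        ]
        epi = cls(
            population=np.asarray(d["population"], dtype=float),
            mortality=np.asarray(d["mortality"], dtype=float),
            bmi_median=np.asarray(d["bmi_median"], dtype=float),
            bmi_dispersion=np.asarray(d["bmi_dispersion"], dtype=float),
            height_m=np.asarray(d["height_m"], dtype=float),
            utility=np.asarray(d["utility"], dtype=float),
            diseases=diseases,
            other_cause_cost=float(d.get("other_cause_cost", 0.0)),
            social_care_cost=float(d.get("social_care_cost", 0.0)),
            social_care_age=int(d.get("social_care_age", 85)),
            other_cause_cost_ci=tuple(d["other_cause_cost_ci"]) if d.get("other_cause_cost_ci") else None,
            social_care_cost_ci=tuple(d["social_care_cost_ci"]) if d.get("social_care_cost_ci") else None,
            d0_ci=tuple(d["d0_ci"]) if d.get("d0_ci") else None,
            discount_rate=float(d.get("discount_rate", 0.035)),
            baseline_year=int(d.get("baseline_year", 2017)),
            b_ref=float(d.get("b_ref", 21.0)),
            eligible_bmi=float(d.get("eligible_bmi", 30.0)),
        )
        epi.validate()
        return epi

    def save(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "EpiInputs":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def lognormal_bmi_masses(median, dispersion) -> np.ndarray:
    """Cell masses of a lognormal BMI distribution on the 10–60 grid.

    Masses come from CDF differences over cell edges, renormalized over the
    grid so each stratum integrates to exactly 1 (the mass outside 10–60
    kg/m² is negligible for realistic parameters).
    """
    mu = np.log(np.asarray(median, dtype=float))[..., None]
    sig = np.asarray(dispersion, dtype=float)[..., None]
    cdf = stats.norm.cdf((np.log(BMI_GRID_EDGES) - mu) / sig)
    masses = np.diff(cdf, axis=-1)
    total = masses.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise IntegrityError("BMI distribution has no mass on the 10-60 grid")
    return masses / total


# ---------------------------------------------------------------------------
# Population impact fraction
# ---------------------------------------------------------------------------


def pif(
    bmi_masses: np.ndarray,
    delta_bmi,
    rr: float | Callable[[np.ndarray], np.ndarray],
    grid: np.ndarray | None = None,
    b_ref: float = 21.0,
    eligible_min: float = 30.0,
) -> np.ndarray:
    """Population impact fraction for a BMI shift of the eligible mass.

    PIF = 1 − ∫p'(b)RR(b)db / ∫p(b)RR(b)db, where p' moves the mass at
    b ≥ ``eligible_min`` by ``delta_bmi`` (≤ 0).  ``rr`` is either the
    relative risk per BMI unit above ``b_ref`` (RR(b) = rr^max(0, b−b_ref))
    or an arbitrary callable RR(b).  ``bmi_masses``' last axis must sum to
    1 within 1e-6; ``delta_bmi`` broadcasts against the leading axes.
    """
    masses = np.asarray(bmi_masses, dtype=float)
    g = BMI_GRID if grid is None else np.asarray(grid, dtype=float)
    total = masses.sum(axis=-1)
    if np.any(np.abs(total - 1.0) > 1e-6):
        raise IntegrityError("BMI masses must integrate to 1 (within 1e-6) per stratum")
    delta = np.asarray(delta_bmi, dtype=float)[..., None]
    shifted = g + delta * (g >= eligible_min)
    if callable(rr):
        rr_base = rr(np.broadcast_to(g, masses.shape))
        rr_shift = rr(np.broadcast_to(shifted, np.broadcast_shapes(shifted.shape, masses.shape)))
    else:
        lnrr = np.log(rr)
        rr_base = np.exp(lnrr * np.maximum(g - b_ref, 0.0))
        rr_shift = np.exp(lnrr * np.maximum(shifted - b_ref, 0.0))
    denom = (masses * rr_base).sum(axis=-1)
    num = (masses * rr_shift).sum(axis=-1)
    return 1.0 - num / denom


# ---------------------------------------------------------------------------
# Single-disease difference equations
# ---------------------------------------------------------------------------


def run_disease(
    incidence,
    case_fatality,
    pif_schedule,
    n_years: int,
    c0: float = 0.0,
) -> dict:
    """Three-state annual difference equations for one disease, one cohort.

    With susceptible S and cases C (fractions of the entering cohort):
    ``C(y+1) = C(y) + i·(1−PIF(y))·S(y) − f·C(y)`` and
    ``S(y+1) = S(y) − i·(1−PIF(y))·S(y)``; the leak f·C is death from the
    disease.  ``incidence``/``case_fatality``/``pif_schedule`` may be
    scalars or per-year arrays.  Returns yearly S, C, prevalence among the
    disease-alive (C/(S+C)) and the disease mortality rate f·prevalence.
    """
    i = np.broadcast_to(np.asarray(incidence, dtype=float), (n_years,))
    f = np.broadcast_to(np.asarray(case_fatality, dtype=float), (n_years,))
    pf = np.broadcast_to(np.asarray(pif_schedule, dtype=float), (n_years,))
    S = np.empty(n_years + 1)
    C = np.empty(n_years + 1)
    S[0], C[0] = 1.0 - c0, c0
    for y in range(n_years):
        new = i[y] * (1.0 - pf[y]) * S[y]
        S[y + 1] = S[y] - new
        C[y + 1] = C[y] + new - f[y] * C[y]
        if S[y + 1] < 0 or C[y + 1] < 0:
            raise StabilityError(
                f"negative state at year {y}: annual rates too large for the Euler step"
            )
    alive = S + C
    prev = np.divide(C, alive, out=np.zeros_like(C), where=alive > 0)
    dmort = np.concatenate([f, [f[-1]]]) * prev
    return {"S": S, "C": C, "prevalence": prev, "disease_mortality": dmort}


# ---------------------------------------------------------------------------
# Full lifetable
# ---------------------------------------------------------------------------


@dataclass
class ScenarioResult:
    """Discounted totals (whole population) plus optional per-year traces."""

    person_years: float
    qalys: float
    health_costs: float
    social_costs: float
    traces: dict | None = None

    def total_costs(self, perspective: Literal["health", "health_social"]) -> float:
        if perspective == "health":
            return self.health_costs
        if perspective == "health_social":
            return self.health_costs + self.social_costs
        raise ValueError(f"unknown perspective {perspective!r}")


def _pif_tables(epi: EpiInputs, d_mid: np.ndarray) -> np.ndarray:
    """PIF per (year, disease, sex, age-at-baseline); cached over repeated D values."""
    n_years = d_mid.size
    nd = len(epi.diseases)
    masses = epi.bmi_masses()
    h2 = epi.height_m**2
    out = np.zeros((n_years, nd, *h2.shape))
    cache: dict[float, np.ndarray] = {}
    for y in range(n_years):
        dkg = float(d_mid[y])
        if dkg == 0.0:
            continue
        key = round(dkg, 12)
        if key not in cache:
            delta = dkg / h2
            cache[key] = np.stack(
                [
                    pif(masses, delta, d.rr_per_bmi_unit,
                        b_ref=epi.b_ref, eligible_min=epi.eligible_bmi)
                    for d in epi.diseases
                ]
            )
        out[y] = cache[key]
    return out


def _simulate(
    epi: EpiInputs,
    pif_tab: np.ndarray | None,
    dm_ref: np.ndarray | None = None,
):
    """March every baseline cohort (sex × starting age) through annual cycles.

    ``pif_tab`` is None for the reference scenario.  For the intervention,
    all-cause mortality is the reference mortality minus the sum over
    diseases of the reference-minus-intervention disease mortality, which
    requires the reference disease-mortality trace ``dm_ref``.
    Returns survivorship l (Y+1), person-years py (Y), disease prevalence
    prev (Y, nd) and disease mortality dm (Y, nd), each per stratum.
    """
    nsex, nage = epi.population.shape
    nd = len(epi.diseases)
    n_years = AGE_MAX - AGE_MIN  # cohorts close at age 100
    a0 = np.arange(nage)[None, :].repeat(nsex, axis=0)

    inc = np.stack([d.incidence for d in epi.diseases]) if nd else np.zeros((0, nsex, nage))
    fat = np.stack([d.case_fatality for d in epi.diseases]) if nd else np.zeros((0, nsex, nage))

    l = np.ones((n_years + 1, nsex, nage))
    py = np.zeros((n_years, nsex, nage))
    prev_tr = np.zeros((n_years, nd, nsex, nage))
    dm_tr = np.zeros((n_years, nd, nsex, nage))

    S = np.ones((nd, nsex, nage))
    C = np.zeros((nd, nsex, nage))
    sex_ix = np.arange(nsex)[:, None]

    for y in range(n_years):
        age_ix = a0 + y
        active = age_ix <= (AGE_MAX - AGE_MIN - 1)  # current age <= 99
        ai = np.minimum(age_ix, nage - 1)

        alive_dc = S + C
        prev = np.divide(C, alive_dc, out=np.zeros_like(C), where=alive_dc > 0)
        f_now = np.where(active, fat[:, sex_ix, ai], 0.0)
        dm = f_now * prev
        prev_tr[y] = prev
        dm_tr[y] = dm

        q = epi.mortality[sex_ix, ai].copy()
        if dm_ref is not None:
            q = q - (dm_ref[y].sum(axis=0) - dm.sum(axis=0))
        if np.any((q[active] < 0) | (q[active] > 1)):
            raise StabilityError(f"all-cause death probability outside [0, 1] at year {y}")
        q = np.where(active, q, 0.0)

        l[y + 1] = l[y] * (1.0 - q)
        py[y] = np.where(active, 0.5 * (l[y] + l[y + 1]), 0.0)

        i_now = np.where(active, inc[:, sex_ix, ai], 0.0)
        if pif_tab is not None:
            i_now = i_now * (1.0 - pif_tab[y])
        new = i_now * S
        S = S - new
        C = C + new - f_now * C
        if np.any(S[:, active] < -1e-12) or np.any(C[:, active] < -1e-12):
            raise StabilityError(
                f"negative disease state at year {y}: rates too large for the annual step"
            )

    return {"l": l, "py": py, "prev": prev_tr, "dm": dm_tr}


def _aggregate(tr: dict, epi: EpiInputs, keep_traces: bool) -> ScenarioResult:
    n_years = tr["py"].shape[0]
    nd = len(epi.diseases)
    dec = np.array([d.utility_decrement for d in epi.diseases]).reshape(nd, 1, 1)
    dcost = np.array([d.annual_cost for d in epi.diseases]).reshape(nd, 1, 1)

    nsex, nage = epi.population.shape
    disc = (1.0 + epi.discount_rate) ** -(np.arange(n_years) + 0.5)
    pop = epi.population

    # current-age index per (year, sex, stratum), clipped at the age cap
    ai = np.minimum(np.arange(n_years)[:, None, None] + np.arange(nage)[None, None, :],
                    nage - 1)
    ai = np.broadcast_to(ai, (n_years, nsex, nage))
    util_raw = epi.utility[np.arange(nsex)[None, :, None], ai]
    comorbid = (tr["prev"] * dec).sum(axis=1)
    util = util_raw - comorbid
    if np.any((util < 0) & (tr["py"] > 0)):
        warnings.warn("utility floored at 0 in some stratum-years (comorbidity overload)")
    util = np.clip(util, 0.0, None)

    py_w = tr["py"] * pop  # person-years by stratum-year
    person_years = float(np.einsum("ysa,y->", py_w, disc))
    qalys = float(np.einsum("ysa,y->", py_w * util, disc))

    disease_cost = (tr["prev"] * dcost).sum(axis=1)
    health = float(np.einsum("ysa,y->", py_w * (disease_cost + epi.other_cause_cost), disc))
    # old-age social care scales with disability (1 - utility): healthier
    # survivors need less care, so prevention can save care costs even
    # while it adds life years
    old = (ai + AGE_MIN) >= epi.social_care_age
    social = float(
        np.einsum("ysa,y->", py_w * old * (1.0 - util) * epi.social_care_cost, disc)
    )

    return ScenarioResult(
        person_years=person_years,
        qalys=qalys,
        health_costs=health,
        social_costs=social,
        traces=tr if keep_traces else None,
    )


def run_lifetable(
    epi: EpiInputs,
    trajectory: Trajectory | None,
    perspective: Literal["health", "health_social"] = "health",
    programme_end_month: float = 6.0,
    keep_traces: bool = True,
    _ref_traces: dict | None = None,
) -> tuple[ScenarioResult, ScenarioResult]:
    """Run the reference and intervention scenarios over all baseline cohorts.

    Returns ``(reference, intervention)`` :class:`ScenarioResult`s; the
    perspective only matters downstream (both cost components are always
    accumulated).  ``_ref_traces`` lets the Monte Carlo layer reuse the
    draw-independent reference simulation.
    """
    epi.validate()
    n_years = AGE_MAX - AGE_MIN
    ref_tr = _ref_traces if _ref_traces is not None else _simulate(epi, None)
    if trajectory is None:
        int_tr = ref_tr
    else:
        d_mid = trajectory.midyear_samples(n_years, programme_end_month)
        pif_tab = _pif_tables(epi, d_mid)
        int_tr = _simulate(epi, pif_tab, dm_ref=ref_tr["dm"])
    res_ref = _aggregate(ref_tr, epi, keep_traces)
    res_int = _aggregate(int_tr, epi, keep_traces)
    return res_ref, res_int


def discount(stream, rate: float, t0: float = 0.0, times=None) -> float:
    """Present value Σ xₜ/(1+rate)^(t−t0) of a dated cash/utility stream.

    ``times`` defaults to 0, 1, 2, … (annual stream starting at ``t0``).
    """
    x = np.asarray(stream, dtype=float)
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    t = np.arange(x.size, dtype=float) if times is None else np.asarray(times, dtype=float)
    return float(np.sum(x * (1.0 + rate) ** -(t - t0)))
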