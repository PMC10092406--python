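"""Synthetic study corpora and toy epidemiology inputs.

The corpus generator emulates the statistical structure of extraction
tables from randomized BWMP trials: programme-end intervention-minus-
control differences centred near −2.8 kg with between-study heterogeneity,
linear post-programme regain, irregular sparse follow-up schedules with
dropout of later visits, recoverable sampling variances, a risk-of-bias
mix, and a QoL subset whose standardized differences track weight regain.

The epidemiology generator produces a fully valid :class:`EpiInputs` toy —
Gompertz all-cause mortality, lognormal BMI with roughly a quarter of
adults above 30 kg/m², four BMI-related diseases and plausible unit costs.
It is a stand-in for real national inputs, not calibrated to any country.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .lifetable import AGE_MAX, AGE_MIN, DiseaseSpec, EpiInputs
from .study_corpus import CSV_COLUMNS

__all__ = ["CorpusParams", "generate_corpus", "EpiParams", "generate_epi"]


@dataclass
class CorpusParams:
    """Knobs of the trial-corpus generator (defaults mirror the observed corpus)."""

    n_studies: int = 50
    mean_d0: float = -2.8  # programme-end difference, kg
    tau_intercept: float = 0.8  # between-study SD of the intercept, kg
    true_slope: float = 0.027  # regain, kg/month
    noise_sd_kg: float = 0.5  # within-study visit-level noise
    n_per_arm: tuple[int, int] = (30, 250)
    programme_length_months: tuple[float, float] = (3.0, 12.0)
    followup_offsets: tuple[float, ...] = (6.0, 12.0, 24.0, 36.0, 60.0)
    dropout_per_visit: float = 0.25  # chance each later visit is lost
    censor_horizon_months: float = 60.0  # post-programme
    qol_fraction: float = 0.25
    qol_slope_smd_per_kg: float = -0.02
    qol_noise_sd_smd: float = 0.05
    qol_smd_at_programme_end: float = 0.21
    rob_mix: tuple[float, float, float] = (0.23, 0.53, 0.24)  # low/unclear/high
    seed: int = 0

    def __post_init__(self):
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        for name in ("tau_intercept", "noise_sd_kg", "qol_noise_sd_smd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mean_d0 >= 0:
            warnings.warn(
                "mean_d0 >= 0: most generated studies will fail the regain-eligibility filter"
            )


def generate_corpus(params: CorpusParams | None = None, **kw) -> pd.DataFrame:
    """A studies.csv-conformant table of synthetic two-arm trials.

    Study j has programme-end difference a_j ~ N(mean_d0, τ²) and follows
    D_j(t) = a_j + slope·t + ε (ε visit-level noise) at programme end plus
    a sparse post-programme schedule; the difference is realized as control
    and intervention arm series with emitted SDs and n so that sampling
    variances are recoverable downstream.  Deterministic given the seed.
    """
    p = params if params is not None else CorpusParams(**kw)
    rng = np.random.default_rng(p.seed)
    rows = []
    rob_levels = np.array(["low", "unclear", "high"])
    for j in range(p.n_studies):
        sid = f"S{j + 1:04d}"
        pe = float(np.round(rng.uniform(*p.programme_length_months), 1))
        a_j = rng.normal(p.mean_d0, p.tau_intercept)
        rob = str(rng.choice(rob_levels, p=np.asarray(p.rob_mix) / np.sum(p.rob_mix)))
        n_c = int(rng.integers(*p.n_per_arm))
        n_i = int(rng.integers(*p.n_per_arm))
        sd_c = float(np.round(rng.uniform(2.5, 4.5), 2))
        sd_i = float(np.round(rng.uniform(2.5, 4.5), 2))

        t_rel = [0.0]
        for off in p.followup_offsets:
            if off > p.censor_horizon_months:
                break
            if rng.random() < p.dropout_per_visit:
                break
            t_rel.append(float(off))
        if len(t_rel) == 1:  # always keep at least the first post-programme visit
            t_rel.append(float(p.followup_offsets[0]))

        # control arm: loses a little, drifts back toward baseline
        c_pe = rng.normal(-2.1, 1.0)
        c_of = lambda t: c_pe * max(0.0, 1.0 - t / 90.0)

        has_qol = rng.random() < p.qol_fraction
        lower_better = bool(rng.random() < 0.3)
        qol_sd_scale = float(np.round(rng.uniform(15.0, 30.0), 1))
        b_j = (
            p.qol_smd_at_programme_end
            - p.qol_slope_smd_per_kg * p.mean_d0
            + rng.normal(0.0, 0.05)
        )

        for t in t_rel:
            d_t = a_j + p.true_slope * t + rng.normal(0.0, p.noise_sd_kg)
            c_mean = c_of(t)
            i_mean = c_mean + d_t
            qol_c = qol_i = qol_sd = None
            if has_qol:
                smd = b_j + p.qol_slope_smd_per_kg * d_t + rng.normal(0.0, p.qol_noise_sd_smd)
                sign = -1.0 if lower_better else 1.0
                qol_c = float(np.round(rng.normal(1.0, 2.0), 3))
                qol_i = float(np.round(qol_c + sign * smd * qol_sd_scale, 3))
                qol_sd = qol_sd_scale
            for arm_id, role, mean, sd, n, qm in (
                ("control", "control", c_mean, sd_c, n_c, qol_c),
                ("int1", "intervention", i_mean, sd_i, n_i, qol_i),
            ):
                rows.append(
                    {
                        "study_id": sid,
                        "arm_id": arm_id,
                        "arm_role": role,
                        "rob_overall": rob,
                        "programme_end_month": pe,
                        "t_months": pe + t,
                        "mean_change_kg": round(float(mean), 4),
                        "sd_kg": sd,
                        "n_analyzed": n,
                        "qol_scale": (
                            ("IWQOL" if lower_better else "SF-36") if has_qol else None
                        ),
                        "qol_direction": (
                            ("lower_better" if lower_better else "higher_better")
                            if has_qol
                            else None
                        ),
                        "qol_mean_change": qm,
                        "qol_sd": qol_sd,
                    }
                )
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


# ---------------------------------------------------------------------------
# Toy epidemiology
# ---------------------------------------------------------------------------


@dataclass
class EpiParams:
    """Knobs of the toy epidemiology generator."""

    seed: int = 0
    jitter: float = 0.08  # lognormal SD of the per-run parameter wobble
    d0_ci: tuple[float, float] = (1.0, 6.0)  # 95% interval of |d0| across studies


_DISEASES = [
    # name, inc0, inc_slope/yr, sex_mult, cf0, cf_slope, rr, rr_ci, decr, cost
    ("ihd", 5e-5, 0.080, 1.6, 0.030, 0.020, 1.08, (1.04, 1.16), 0.10, 2500.0),
    ("stroke", 2e-5, 0.085, 1.2, 0.050, 0.020, 1.06, (1.03, 1.12), 0.12, 3000.0),
    ("t2dm", None, None, 1.1, 0.005, 0.015, 1.15, (1.08, 1.29), 0.06, 1800.0),
    ("colorectal_cancer", 1e-5, 0.070, 1.3, 0.100, 0.005, 1.03, (1.015, 1.06), 0.15, 12000.0),
]


def generate_epi(params: EpiParams | int | None = None) -> EpiInputs:
    """A valid toy :class:`EpiInputs` for the lifetable.

    Mortality is Gompertz in age with a male excess; BMI is lognormal per
    stratum with a gentle age trend putting ~25% of adults above 30 kg/m²;
    four diseases carry relative risks per BMI unit between 1.03 and 1.15.
    A small seed-dependent jitter varies the toy between runs without
    breaking any invariant.
    """
    if params is None:
        params = EpiParams()
    if isinstance(params, int):
        params = EpiParams(seed=params)
    rng = np.random.default_rng(params.seed)
    jit = lambda: float(np.exp(rng.normal(0.0, params.jitter)))

    ages = np.arange(AGE_MIN, AGE_MAX + 1, dtype=float)
    rel = ages - AGE_MIN
    nage = ages.size

    mort_f = 4.5e-4 * jit() * np.exp(0.075 * rel)
    mortality = np.clip(np.stack([mort_f, 1.5 * mort_f]), 0.0, 0.95)

    bmi_median = np.stack(
        [
            24.5 * jit() + 3.5 * np.clip(rel / 37.0, 0.0, 1.0),
            24.8 * jit() + 3.2 * np.clip(rel / 37.0, 0.0, 1.0),
        ]
    )
    bmi_dispersion = np.full((2, nage), 0.16 * jit())
    height_m = np.stack(
        [1.63 - 0.06 * rel / 82.0, 1.77 - 0.06 * rel / 82.0]
    )
    utility = np.stack(
        [0.94 - 0.20 * rel / 82.0, 0.93 - 0.20 * rel / 82.0]
    )
    population = 100_000.0 * np.exp(-0.5 * ((ages - 45.0) / 32.0) ** 2)
    population = np.stack([population, 0.97 * population])

    diseases = []
    for name, inc0, slope, sexm, cf0, cfs, rr, rr_ci, dec, cost in _DISEASES:
        if inc0 is None:  # t2dm: midlife incidence bump
            inc_f = 2.0e-3 * jit() * np.exp(-0.5 * ((ages - 60.0) / 15.0) ** 2)
        else:
            inc_f = inc0 * jit() * np.exp(slope * rel)
        incidence = np.clip(np.stack([inc_f, sexm * inc_f]), 0.0, 0.5)
        cf = np.clip(cf0 * jit() * np.exp(cfs * rel), 0.0, 0.8)
        case_fatality = np.stack([cf, cf])
        diseases.append(
            DiseaseSpec(
                name=name,
                incidence=incidence,
                case_fatality=case_fatality,
                rr_per_bmi_unit=rr,
                utility_decrement=dec,
                annual_cost=cost,
                rr_ci=rr_ci,
                annual_cost_ci=(cost / 2.0, cost * 2.0),
                utility_decrement_sd=0.1 * dec,
            )
        )

    epi = EpiInputs(
        population=population,
        mortality=mortality,
        bmi_median=bmi_median,
        bmi_dispersion=bmi_dispersion,
        height_m=height_m,
        utility=utility,
        diseases=diseases,
        other_cause_cost=1300.0,
        social_care_cost=8000.0,
        social_care_age=85,
        other_cause_cost_ci=(650.0, 2600.0),
        social_care_cost_ci=(4000.0, 16000.0),
        d0_ci=params.d0_ci,
        discount_rate=0.035,
        baseline_year=2017,
    )
    epi.validate()
    return epi
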