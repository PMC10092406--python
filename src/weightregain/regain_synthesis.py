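"""Synthesis of post-programme weight-regain (and QoL) trajectories.

Three complementary models of the intervention-minus-control difference
series after programme end:

* **model 1** (:func:`fit_mixed`) — linear mixed model with a random
  intercept per study, fitted by restricted maximum likelihood (REML) on
  every available time point, observations weighted by inverse sampling
  variance (or by total n when variances are largely unreported);
* **model 2** (:func:`fit_metareg`) — random-effects meta-regression of the
  final-follow-up difference on time since programme end, REML between-study
  variance, weights 1/(vᵢ + τ²);
* **model 3** (:func:`crossing_times` + :func:`km_estimate`) — study-level
  time-to-event synthesis: the first (linearly interpolated) time each
  study's difference reaches zero, summarized by the Kaplan–Meier
  product-limit estimator and its median.

QoL differences are standardized to SMDs against the pooled change-score SD
(:func:`standardize_qol`), back-convertible to SF-36 points
(:func:`smd_to_sf36`); :func:`qol_weight_slope` links QoL to weight regain
through the model-1 machinery, and :func:`followup_bias_check` screens for
publication bias via the follow-up-length / programme-end-loss association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import EstimationError
from .study_corpus import Corpus, DifferenceSeries, build_difference_series

__all__ = [
    "RegainFit",
    "CrossingRecord",
    "KMResult",
    "fit_mixed",
    "fit_metareg",
    "crossing_times",
    "km_estimate",
    "standardize_qol",
    "smd_to_sf36",
    "qol_weight_slope",
    "followup_bias_check",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class RegainFit:
    """A fitted linear difference model: difference = intercept + slope·t."""

    model: Literal["mixed", "metareg"]
    outcome: str
    intercept: float
    slope: float
    ci95_intercept: tuple[float, float]
    ci95_slope: tuple[float, float]
    se_intercept: float
    se_slope: float
    tau2: float
    n_studies: int
    n_points: int
    p_slope: float = float("nan")

    def predict(self, t_months) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t_months, dtype=float)


@dataclass(frozen=True)
class CrossingRecord:
    study_id: str
    time_months: float
    event: bool


@dataclass(frozen=True)
class KMResult:
    times: np.ndarray
    survival: np.ndarray
    median_months: float | None


# ---------------------------------------------------------------------------
# Model 1: weighted random-intercept mixed model (REML)
# ---------------------------------------------------------------------------


def _assemble_points(series_list: Sequence[DifferenceSeries]):
    study, t, y, v, n = [], [], [], [], []
    for j, s in enumerate(series_list):
        for ti, di, vi, ni in s.points:
            study.append(j)
            t.append(ti)
            y.append(di)
            v.append(np.nan if vi is None else vi)
            n.append(ni)
    return (
        np.asarray(study, dtype=np.intp),
        np.asarray(t, dtype=float),
        np.asarray(y, dtype=float),
        np.asarray(v, dtype=float),
        np.asarray(n, dtype=float),
    )


def _choose_weights(v: np.ndarray, n: np.ndarray, policy: str) -> np.ndarray:
    """Observation weights per policy.

    ``"auto"`` uses inverse variance when at least 80% of points carry a
    reported variance (the rest filled with the median variance), otherwise
    total analyzed n.  Weights are rescaled to mean 1 so the residual scale
    stays interpretable.
    """
    have = np.isfinite(v) & (v > 0)
    if policy == "auto":
        policy = "inverse_variance" if have.mean() >= 0.8 else "n_total"
    if policy == "inverse_variance":
        if not have.any():
            raise EstimationError("inverse-variance weighting requested but no variances present")
        vv = np.where(have, v, np.median(v[have]))
        w = 1.0 / vv
    elif policy == "n_total":
        w = n.astype(float)
    elif policy == "none":
        w = np.ones_like(v)
    else:
        raise ValueError(f"unknown weights policy {policy!r}")
    return w / w.mean()


def _reml_neg2ll(log_phi, groups, X, y, w, m):
    """−2·REML log-likelihood, profiled over β and the residual scale σ².

    Random-intercept covariance per study block: σ²(W⁻¹ + φ 11′), with
    φ = τ²/σ².  Block inverses via Sherman–Morrison keep every evaluation
    O(n points).
    """
    phi = np.exp(log_phi)
    n, p = X.shape
    s_j = np.bincount(groups, weights=w, minlength=m)  # Σ w within study
    shrink = phi / (1.0 + phi * s_j)  # per-study rank-1 factor

    wX = w[:, None] * X
    wy = w * y
    SX = np.vstack([np.bincount(groups, weights=wX[:, k], minlength=m) for k in range(p)]).T
    Sy = np.bincount(groups, weights=wy, minlength=m)

    A = X.T @ wX - (SX * shrink[:, None]).T @ SX  # X' M⁻¹ X
    b = X.T @ wy - SX.T @ (shrink * Sy)  # X' M⁻¹ y
    yMy = y @ wy - Sy @ (shrink * Sy)

    sign, logdet_A = np.linalg.slogdet(A)
    if sign <= 0:
        return np.inf
    beta = np.linalg.solve(A, b)
    rss = yMy - b @ beta
    if rss <= 0:
        rss = 1e-300
    sigma2 = rss / (n - p)
    logdet_M = -np.sum(np.log(w)) + np.sum(np.log1p(phi * s_j))
    return (n - p) * np.log(sigma2) + logdet_M + logdet_A + (n - p)


def _fit_random_intercept(
    groups: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
):
    """Weighted random-intercept REML fit; returns (beta, cov, sigma2, tau2)."""
    n, p = X.shape
    m = int(groups.max()) + 1 if groups.size else 0
    if n <= p:
        raise EstimationError("not enough observations to fit the mixed model")

    if m < 2:
        # single study: the random intercept is unidentifiable; pure WLS
        phi = 0.0
    else:
        res = optimize.minimize_scalar(
            _reml_neg2ll,
            bounds=(-30.0, 32.0),
            args=(groups, X, y, w, m),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if not np.isfinite(res.fun):
            # method-of-moments fallback on per-study intercept residuals
            phi = _mom_phi(groups, X, y, w, m)
            warnings.warn("REML did not converge; using method-of-moments tau2")
        else:
            phi = float(np.exp(res.x))
            if phi < 1e-10:
                phi = 0.0

    s_j = np.bincount(groups, weights=w, minlength=max(m, 1))
    shrink = phi / (1.0 + phi * s_j)
    wX = w[:, None] * X
    wy = w * y
    SX = np.vstack([np.bincount(groups, weights=wX[:, k], minlength=max(m, 1)) for k in range(p)]).T
    Sy = np.bincount(groups, weights=wy, minlength=max(m, 1))
    A = X.T @ wX - (SX * shrink[:, None]).T @ SX
    b = X.T @ wy - SX.T @ (shrink * Sy)
    sign, _ = np.linalg.slogdet(A)
    if sign <= 0:
        raise EstimationError("design is singular (no variation in the predictor)")
    beta = np.linalg.solve(A, b)
    yMy = y @ wy - Sy @ (shrink * Sy)
    rss = max(yMy - b @ beta, 0.0)
    dof = max(n - p, 1)
    sigma2 = rss / dof
    if sigma2 == 0.0:  # noiseless data: covariance collapses
        cov = np.zeros((p, p))
    else:
        cov = sigma2 * np.linalg.inv(A)
    return beta, cov, sigma2, phi * sigma2


def _mom_phi(groups, X, y, w, m) -> float:
    beta, *_ = np.linalg.lstsq(np.sqrt(w)[:, None] * X, np.sqrt(w) * y, rcond=None)
    resid = y - X @ beta
    means = np.bincount(groups, weights=w * resid, minlength=m) / np.bincount(
        groups, weights=w, minlength=m
    )
    within = resid - means[groups]
    sigma2 = float(np.sum(w * within**2) / max(len(y) - m - X.shape[1], 1))
    tau2 = max(float(np.var(means, ddof=1)) - sigma2 / np.mean(np.bincount(groups)), 0.0)
    return tau2 / sigma2 if sigma2 > 0 else 0.0


def fit_mixed(
    series_list: Sequence[DifferenceSeries],
    weights_policy: Literal["auto", "inverse_variance", "n_total", "none"] = "auto",
    outcome: str | None = None,
) -> RegainFit:
    """Model 1: random-intercept mixed model of differences on months since programme end.

    Every available (study, time) difference contributes one observation;
    the study-level random intercept absorbs between-study heterogeneity in
    programme-end effect (variance ``tau2``).  95% CIs use the normal
    approximation on the REML covariance.
    """
    series_list = list(series_list)
    groups, t, y, v, n = _assemble_points(series_list)
    if t.size == 0:
        raise EstimationError("no observations")
    if np.ptp(t) == 0.0:
        raise EstimationError("all points at the same time; slope inestimable")
    w = _choose_weights(v, n, weights_policy)
    X = np.column_stack([np.ones_like(t), t])
    beta, cov, _sigma2, tau2 = _fit_random_intercept(groups, X, y, w)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = beta[1] / se[1] if se[1] > 0 else np.inf * np.sign(beta[1] or 1.0)
    return RegainFit(
        model="mixed",
        outcome=outcome or series_list[0].outcome,
        intercept=float(beta[0]),
        slope=float(beta[1]),
        ci95_intercept=(float(beta[0] - _Z95 * se[0]), float(beta[0] + _Z95 * se[0])),
        ci95_slope=(float(beta[1] - _Z95 * se[1]), float(beta[1] + _Z95 * se[1])),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        tau2=float(tau2),
        n_studies=len(series_list),
        n_points=int(t.size),
        p_slope=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0,
    )


# ---------------------------------------------------------------------------
# Model 2: random-effects meta-regression (REML)
# ---------------------------------------------------------------------------


def _metareg_reml(y, v, X):
    """REML τ² for yᵢ = Xβ + uᵢ + eᵢ, Var(eᵢ)=vᵢ, Var(uᵢ)=τ²."""
    n, p = X.shape

    def neg2ll(log_tau2):
        tau2 = np.exp(log_tau2)
        wi = 1.0 / (v + tau2)
        A = X.T @ (wi[:, None] * X)
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(A, X.T @ (wi * y))
        r = y - X @ beta
        return float(np.sum(np.log(v + tau2)) + logdet_A + np.sum(wi * r**2))

    res = optimize.minimize_scalar(
        neg2ll, bounds=(np.log(1e-12), np.log(1e4)), method="bounded",
        options={"xatol": 1e-10},
    )
    tau2 = float(np.exp(res.x))
    if tau2 < 1e-10 or neg2ll(np.log(1e-12)) <= res.fun:
        tau2 = 0.0
    wi = 1.0 / (v + tau2)
    A = X.T @ (wi[:, None] * X)
    sign, _ = np.linalg.slogdet(A)
    if sign <= 0:
        raise EstimationError("moderator has no variation; slope inestimable")
    beta = np.linalg.solve(A, X.T @ (wi * y))
    cov = np.linalg.inv(A)
    return beta, cov, tau2


def _final_effects(series_list: Sequence[DifferenceSeries]):
    """Per-study final-follow-up effect, its variance, and the final time."""
    eff, var, tt, n = [], [], [], []
    for s in series_list:
        post = [(t, d, v, nn) for t, d, v, nn in s.points if t > 0]
        if not post:
            continue
        t, d, v, nn = max(post, key=lambda p: p[0])
        eff.append(d)
        var.append(np.nan if v is None else v)
        tt.append(t)
        n.append(nn)
    eff, var, tt, n = map(np.asarray, (eff, var, tt, n))
    have = np.isfinite(var) & (var > 0)
    if have.any():
        # missing variances filled on the 1/n scale anchored to reported ones
        k = np.median(var[have] * n[have])
        var = np.where(have, var, k / n)
    else:
        var = 4.0 / n  # generic change-score variance scale
    return eff, var.astype(float), tt.astype(float)


def fit_metareg(series_list: Sequence[DifferenceSeries], outcome: str | None = None) -> RegainFit:
    """Model 2: random-effects meta-regression of final difference on final time.

    One effect per study (the last post-programme difference), moderated by
    its time since programme end; τ² by REML, weights 1/(vᵢ + τ²).  The
    intercept extrapolates back to programme end.
    """
    series_list = list(series_list)
    y, v, t = _final_effects(series_list)
    if y.size < 3:
        raise EstimationError("meta-regression needs at least 3 studies with post-programme data")
    if np.ptp(t) == 0.0:
        raise EstimationError("all studies share the final follow-up time; slope inestimable")
    X = np.column_stack([np.ones_like(t), t])
    beta, cov, tau2 = _metareg_reml(y, v, X)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = beta[1] / se[1] if se[1] > 0 else np.inf
    return RegainFit(
        model="metareg",
        outcome=outcome or series_list[0].outcome,
        intercept=float(beta[0]),
        slope=float(beta[1]),
        ci95_intercept=(float(beta[0] - _Z95 * se[0]), float(beta[0] + _Z95 * se[0])),
        ci95_slope=(float(beta[1] - _Z95 * se[1]), float(beta[1] + _Z95 * se[1])),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        tau2=tau2,
        n_studies=int(y.size),
        n_points=int(y.size),
        p_slope=float(2 * stats.norm.sf(abs(z))),
    )


# ---------------------------------------------------------------------------
# Model 3: time to no-difference (Kaplan-Meier)
# ---------------------------------------------------------------------------


def crossing_times(series_list: Iterable[DifferenceSeries]) -> list[CrossingRecord]:
    """First time each study's difference reaches zero, by linear interpolation.

    An event occurs on the first segment between consecutive visits where the
    difference goes from negative to ≥ 0; otherwise the study is censored at
    its last visit.
    """
    records = []
    for s in series_list:
        pts = sorted(s.points, key=lambda p: p[0])
        event_t = None
        for (t0, d0, *_), (t1, d1, *_) in zip(pts, pts[1:]):
            if d0 < 0 <= d1:
                event_t = t0 if d1 == d0 else t0 + (0.0 - d0) * (t1 - t0) / (d1 - d0)
                break
        if event_t is not None:
            records.append(CrossingRecord(s.study_id, float(event_t), True))
        else:
            records.append(CrossingRecord(s.study_id, float(pts[-1][0]), False))
    return records


def km_estimate(records: Sequence[CrossingRecord]) -> KMResult:
    """Product-limit survival of "still showing a difference", one unit per study.

    The median is the first time survival drops to ≤ 0.5; ``None`` when the
    curve never reaches 0.5 (heavy censoring).
    """
    if not records:
        raise EstimationError("no crossing records")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(
        [r.time_months for r in records],
        event_observed=[r.event for r in records],
    )
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    median = kmf.median_survival_time_
    median_months = None if np.isinf(median) else float(median)
    return KMResult(times=times, survival=surv, median_months=median_months)


# ---------------------------------------------------------------------------
# Quality of life
# ---------------------------------------------------------------------------


def standardize_qol(corpus: Corpus) -> list[DifferenceSeries]:
    """QoL difference series standardized to SMDs (higher = better).

    SMD = (intervention − control mean change) / pooled change-score SD at
    the matched visit, after direction normalization.  Studies lacking QoL
    SDs are dropped with a warning.  No small-sample (Hedges) correction by
    default.
    """
    out = []
    raw = build_difference_series(corpus, outcome="qol_raw")
    by_study = {s.study_id: s for s in raw}
    for study_id in sorted(by_study):
        meta = corpus.studies[study_id]
        arms = corpus.arms_of(study_id)
        flip = -1.0 if meta.qol_direction == "lower_better" else 1.0
        control = [a for a in arms if a.arm_role == "control" and a.qol_mean_change is not None]
        ints = [a for a in arms if a.arm_role == "intervention" and a.qol_mean_change is not None]
        if not control or not ints:
            continue
        pts = []
        dropped = False
        for c in control:
            cand = [a for a in ints if abs(a.t_months - c.t_months) <= 0.5]
            if not cand:
                continue
            if c.qol_sd is None or any(a.qol_sd is None for a in cand):
                dropped = True
                continue
            ni = np.array([a.n_analyzed for a in cand], dtype=float)
            mi = float(np.average([a.qol_mean_change for a in cand], weights=ni))
            sdi2 = float(np.average([a.qol_sd**2 for a in cand], weights=ni))
            n_i, n_c = ni.sum(), c.n_analyzed
            sp2 = ((n_i - 1) * sdi2 + (n_c - 1) * c.qol_sd**2) / (n_i + n_c - 2)
            if sp2 <= 0:
                dropped = True
                continue
            smd = flip * (mi - c.qol_mean_change) / np.sqrt(sp2)
            var = (n_i + n_c) / (n_i * n_c) + smd**2 / (2 * (n_i + n_c))
            pts.append((c.t_months - meta.programme_end_month, float(smd), float(var),
                        int(n_i + n_c)))
        if dropped and not pts:
            warnings.warn(f"study {study_id!r}: QoL SDs missing; dropped from QoL set")
            continue
        i0 = next((k for k, p in enumerate(pts) if abs(p[0]) <= 0.5), None)
        if i0 is None:
            continue
        pts[i0] = (0.0, *pts[i0][1:])
        pts = sorted((p for p in pts if p[0] >= 0.0), key=lambda p: p[0])
        out.append(
            DifferenceSeries(
                study_id=study_id,
                outcome="qol_smd",
                points=tuple(pts),
                max_followup_months=meta.max_followup_months,
            )
        )
    return out


def smd_to_sf36(smd: float, sf36_sds: Sequence[float]) -> dict:
    """Back-convert an SMD to SF-36 points using per-study SF-36 SDs.

    Returns the per-study point differences and their median and IQR — the
    common-unit illustration for a multi-scale QoL synthesis.
    """
    sds = np.asarray(list(sf36_sds), dtype=float)
    if sds.size == 0:
        raise EstimationError("no SF-36 SDs supplied")
    pts = smd * sds
    q1, med, q3 = np.percentile(pts, [25, 50, 75])
    return {
        "points": pts,
        "median": float(med),
        "iqr": (float(q1), float(q3)),
    }


def qol_weight_slope(
    qol_series: Sequence[DifferenceSeries],
    weight_series: Sequence[DifferenceSeries],
) -> RegainFit:
    """SMD change per kg of weight difference, with random study intercepts.

    Pairs QoL and weight observations of the same study at the same time
    since programme end (±0.5 month) and regresses QoL SMD difference on
    weight difference using the model-1 machinery.  A negative slope means
    QoL erodes as the weight advantage erodes.
    """
    wmap = {s.study_id: s for s in weight_series}
    paired: list[DifferenceSeries] = []
    for q in qol_series:
        w = wmap.get(q.study_id)
        if w is None:
            continue
        pts = []
        for tq, dq, vq, nq in q.points:
            match = [p for p in w.points if abs(p[0] - tq) <= 0.5]
            if not match:
                continue
            _, dw, _, _ = min(match, key=lambda p: abs(p[0] - tq))
            # abuse the t slot to carry the weight difference as predictor
            pts.append((dw, dq, vq, nq))
        if pts:
            paired.append(
                DifferenceSeries(study_id=q.study_id, outcome="qol_smd", points=tuple(pts))
            )
    n_pairs = sum(len(s.points) for s in paired)
    if n_pairs < 2:
        raise EstimationError("fewer than 2 paired QoL/weight observations")
    groups, x, y, v, n = _assemble_points(paired)
    if np.ptp(x) == 0.0:
        raise EstimationError("weight differences constant; slope inestimable")
    w = _choose_weights(v, n, "auto")
    X = np.column_stack([np.ones_like(x), x])
    beta, cov, _s2, tau2 = _fit_random_intercept(groups, X, y, w)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = beta[1] / se[1] if se[1] > 0 else np.inf
    return RegainFit(
        model="mixed",
        outcome="qol_smd_per_kg",
        intercept=float(beta[0]),
        slope=float(beta[1]),
        ci95_intercept=(float(beta[0] - _Z95 * se[0]), float(beta[0] + _Z95 * se[0])),
        ci95_slope=(float(beta[1] - _Z95 * se[1]), float(beta[1] + _Z95 * se[1])),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        tau2=float(tau2),
        n_studies=len(paired),
        n_points=int(n_pairs),
        p_slope=float(2 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0,
    )


# ---------------------------------------------------------------------------
# Publication-bias screen
# ---------------------------------------------------------------------------


def followup_bias_check(series_list: Sequence[DifferenceSeries]) -> RegainFit:
    """Association of programme-end difference with length of follow-up.

    Small-study-style publication-bias screen: if studies with unimpressive
    programme-end losses stop following participants, follow-up length and
    programme-end difference correlate.  Random-effects meta-regression of
    the t = 0 difference on max follow-up (months); a CI covering zero is
    reassuring.
    """
    series_list = [s for s in series_list if any(t == 0 for t, *_ in s.points)]
    if len(series_list) < 3:
        raise EstimationError("bias check needs at least 3 studies")
    y, v, fu = [], [], []
    for s in series_list:
        t0 = next(p for p in s.points if p[0] == 0.0)
        y.append(t0[1])
        v.append(np.nan if t0[2] is None else t0[2])
        fu.append(s.max_followup_months)
    y, v, fu = map(lambda a: np.asarray(a, dtype=float), (y, v, fu))
    if np.ptp(fu[np.isfinite(fu)]) == 0.0:
        raise EstimationError("follow-up constant across studies; slope inestimable")
    have = np.isfinite(v) & (v > 0)
    if have.any():
        v = np.where(have, v, np.median(v[have]))
    else:
        v = np.ones_like(y)
    X = np.column_stack([np.ones_like(fu), fu])
    beta, cov, tau2 = _metareg_reml(y, v, X)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    z = beta[1] / se[1] if se[1] > 0 else np.inf
    return RegainFit(
        model="metareg",
        outcome="d0_on_followup",
        intercept=float(beta[0]),
        slope=float(beta[1]),
        ci95_intercept=(float(beta[0] - _Z95 * se[0]), float(beta[0] + _Z95 * se[0])),
        ci95_slope=(float(beta[1] - _Z95 * se[1]), float(beta[1] + _Z95 * se[1])),
        se_intercept=float(se[0]),
        se_slope=float(se[1]),
        tau2=tau2,
        n_studies=int(y.size),
        n_points=int(y.size),
        p_slope=float(2 * stats.norm.sf(abs(z))),
    )
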