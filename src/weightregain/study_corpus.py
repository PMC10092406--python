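"""Study-level corpus: data model, CSV IO, eligibility filters, difference series.

The corpus holds per-arm longitudinal mean weight (and optionally
quality-of-life) changes from randomized trials of behavioural weight
management programmes (BWMPs).  Each study has one control arm and one or
more intervention arms, observed at months since randomization.  The unit
of synthesis downstream is the intervention-minus-control *difference
series*, re-clocked to months since programme end (the point at which
contact intensity steps down).

Sign conventions: weight change is negative for loss throughout; QoL is
normalized at build time so that higher always means better.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError

__all__ = [
    "ArmObservation",
    "StudyMeta",
    "DifferenceSeries",
    "Corpus",
    "load_corpus",
    "write_corpus",
    "build_difference_series",
    "filter_regain_eligible",
    "filter_by_rob",
    "CSV_COLUMNS",
]

#: Documented studies.csv schema, in canonical column order.
CSV_COLUMNS = [
    "study_id",
    "arm_id",
    "arm_role",
    "rob_overall",
    "programme_end_month",
    "t_months",
    "mean_change_kg",
    "sd_kg",
    "n_analyzed",
    "qol_scale",
    "qol_direction",
    "qol_mean_change",
    "qol_sd",
]

_MANDATORY_NUMERIC = ["programme_end_month", "t_months", "mean_change_kg", "n_analyzed"]

#: Tolerance (months) when matching intervention and control visit times.
TIME_MATCH_TOL = 0.5

ROB_LEVELS = ("low", "unclear", "high")


@dataclass(frozen=True)
class ArmObservation:
    """One arm at one follow-up time.

    ``mean_change_kg`` is the mean weight change from baseline (negative =
    loss).  ``sd_kg`` may be ``None`` when the study did not report it.
    """

    study_id: str
    arm_id: str
    arm_role: Literal["intervention", "control"]
    t_months: float
    mean_change_kg: float
    sd_kg: float | None
    n_analyzed: int
    qol_mean_change: float | None = None
    qol_sd: float | None = None


@dataclass(frozen=True)
class StudyMeta:
    study_id: str
    programme_end_month: float
    max_followup_months: float
    rob_overall: Literal["low", "unclear", "high"]
    qol_scale: str | None = None
    qol_direction: Literal["higher_better", "lower_better"] | None = None


@dataclass(frozen=True)
class DifferenceSeries:
    """Intervention-minus-control differences clocked from programme end.

    ``points`` rows are ``(t_since_programme_end, difference, variance, n_total)``
    with ``variance`` possibly ``None``.  Exactly one point sits at t = 0.
    """

    study_id: str
    outcome: Literal["weight_kg", "qol_smd", "qol_raw"]
    points: tuple[tuple[float, float, float | None, int], ...]
    max_followup_months: float = float("nan")

    @property
    def t(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    @property
    def diff(self) -> np.ndarray:
        return np.array([p[1] for p in self.points], dtype=float)

    @property
    def variance(self) -> np.ndarray:
        return np.array(
            [np.nan if p[2] is None else p[2] for p in self.points], dtype=float
        )

    @property
    def n_total(self) -> np.ndarray:
        return np.array([p[3] for p in self.points], dtype=float)

    def at_programme_end(self) -> float:
        for t, d, _, _ in self.points:
            if t == 0.0:
                return d
        raise IntegrityError(f"series {self.study_id!r} has no t=0 point")


@dataclass
class Corpus:
    """Typed container of arm observations plus per-study metadata."""

    arms: list[ArmObservation] = field(default_factory=list)
    studies: dict[str, StudyMeta] = field(default_factory=dict)

    @property
    def n_studies(self) -> int:
        return len(self.studies)

    @property
    def n_arms(self) -> int:
        return len({(a.study_id, a.arm_id) for a in self.arms})

    def arms_of(self, study_id: str) -> list[ArmObservation]:
        return [a for a in self.arms if a.study_id == study_id]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.arms:
            meta = self.studies[a.study_id]
            rows.append(
                {
                    "study_id": a.study_id,
                    "arm_id": a.arm_id,
                    "arm_role": a.arm_role,
                    "rob_overall": meta.rob_overall,
                    "programme_end_month": meta.programme_end_month,
                    "t_months": a.t_months,
                    "mean_change_kg": a.mean_change_kg,
                    "sd_kg": a.sd_kg,
                    "n_analyzed": a.n_analyzed,
                    "qol_scale": meta.qol_scale,
                    "qol_direction": meta.qol_direction,
                    "qol_mean_change": a.qol_mean_change,
                    "qol_sd": a.qol_sd,
                }
            )
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _corpus_from_frame(df: pd.DataFrame, source: str = "<frame>") -> Corpus:
    df = df.copy()
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing mandatory column(s) {missing}")

    # Coerce numerics; reject rows with unparseable mandatory values.
    bad_rows: list[tuple[int, str]] = []
    for col in _MANDATORY_NUMERIC + ["sd_kg", "qol_mean_change", "qol_sd"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if col in _MANDATORY_NUMERIC:
            newly_bad = df.index[coerced.isna() & df[col].notna()].tolist()
            newly_bad += df.index[df[col].isna()].tolist()
            for i in sorted(set(newly_bad)):
                bad_rows.append((int(i), col))
        df[col] = coerced
    if bad_rows:
        for i, col in bad_rows:
            warnings.warn(
                f"{source}: row {i}: unparseable or missing {col!r}; row rejected",
                stacklevel=3,
            )
        df = df.drop(index=sorted({i for i, _ in bad_rows}))
    if df.empty:
        return Corpus()

    dup = df.duplicated(subset=["study_id", "arm_id", "t_months"], keep=False)
    if dup.any():
        keys = df.loc[dup, ["study_id", "arm_id", "t_months"]].drop_duplicates()
        raise IntegrityError(
            f"{source}: duplicate (study, arm, t) rows: {keys.values.tolist()}"
        )
    if (df["n_analyzed"] < 1).any():
        rows = df.index[df["n_analyzed"] < 1].tolist()
        raise IntegrityError(f"{source}: n_analyzed < 1 in rows {rows}")
    bad_role = ~df["arm_role"].isin(["intervention", "control"])
    if bad_role.any():
        raise SchemaError(
            f"{source}: unknown arm_role {df.loc[bad_role, 'arm_role'].unique().tolist()}"
        )
    sd_bad = df["sd_kg"].notna() & (df["sd_kg"] <= 0)
    if sd_bad.any():
        raise IntegrityError(f"{source}: non-positive sd_kg in rows {df.index[sd_bad].tolist()}")

    corpus = Corpus()
    for study_id, g in df.groupby("study_id", sort=True):
        n_control = g.loc[g["arm_role"] == "control", "arm_id"].nunique()
        if n_control > 1:
            raise IntegrityError(f"{source}: study {study_id!r} has {n_control} control arms")
        rob = str(g["rob_overall"].iloc[0])
        if rob not in ROB_LEVELS:
            raise SchemaError(f"{source}: study {study_id!r} has rob_overall {rob!r}")
        qscale = g["qol_scale"].iloc[0]
        qdir = g["qol_direction"].iloc[0]
        meta = StudyMeta(
            study_id=str(study_id),
            programme_end_month=float(g["programme_end_month"].iloc[0]),
            max_followup_months=float(g["t_months"].max()),
            rob_overall=rob,  # type: ignore[arg-type]
            qol_scale=None if pd.isna(qscale) else str(qscale),
            qol_direction=None if pd.isna(qdir) else str(qdir),  # type: ignore[arg-type]
        )
        corpus.studies[meta.study_id] = meta
        for _, row in g.sort_values(["arm_id", "t_months"]).iterrows():
            corpus.arms.append(
                ArmObservation(
                    study_id=str(study_id),
                    arm_id=str(row["arm_id"]),
                    arm_role=row["arm_role"],
                    t_months=float(row["t_months"]),
                    mean_change_kg=float(row["mean_change_kg"]),
                    sd_kg=None if pd.isna(row["sd_kg"]) else float(row["sd_kg"]),
                    n_analyzed=int(row["n_analyzed"]),
                    qol_mean_change=(
                        None if pd.isna(row["qol_mean_change"]) else float(row["qol_mean_change"])
                    ),
                    qol_sd=None if pd.isna(row["qol_sd"]) else float(row["qol_sd"]),
                )
            )
    return corpus


def load_corpus(path) -> Corpus:
    """Read a studies.csv file (documented schema) into a typed :class:`Corpus`.

    Rows with unparseable mandatory numerics are rejected with a row-level
    warning; a missing mandatory column raises :class:`SchemaError`; a
    duplicate (study, arm, t) key or an invariant violation raises
    :class:`IntegrityError`.
    """
    if isinstance(path, (str, bytes)) or hasattr(path, "__fspath__"):
        df = pd.read_csv(path, dtype={"study_id": str, "arm_id": str})
        source = str(path)
    else:  # file-like
        df = pd.read_csv(path, dtype={"study_id": str, "arm_id": str})
        source = "<stream>"
    return _corpus_from_frame(df, source)


def write_corpus(corpus: Corpus, path) -> None:
    """Write a corpus back to the documented CSV schema (round-trip safe)."""
    corpus.to_frame().to_csv(path, index=False)


def corpus_from_frame(df: pd.DataFrame) -> Corpus:
    """Build a corpus directly from an in-memory schema-conformant frame."""
    return _corpus_from_frame(df)


# ---------------------------------------------------------------------------
# Difference series construction
# ---------------------------------------------------------------------------


def _match_time(ts: Sequence[float], target: float, tol: float = TIME_MATCH_TOL):
    """Index of the visit closest to ``target`` within ``tol``, else None."""
    ts = np.asarray(ts, dtype=float)
    if ts.size == 0:
        return None
    i = int(np.argmin(np.abs(ts - target)))
    return i if abs(ts[i] - target) <= tol else None


def _arm_outcome(obs: ArmObservation, outcome: str) -> tuple[float | None, float | None]:
    if outcome == "weight_kg":
        return obs.mean_change_kg, obs.sd_kg
    return obs.qol_mean_change, obs.qol_sd


def build_difference_series(
    corpus: Corpus,
    outcome: Literal["weight_kg", "qol_raw"] = "weight_kg",
    multi_arm: Literal["n_weighted", "most_intensive"] = "n_weighted",
) -> list[DifferenceSeries]:
    """Intervention-minus-control differences, re-clocked to programme end.

    Control and intervention visits are matched within ±0.5 month.  Studies
    with several intervention arms are pooled by n-weighted average of arm
    means (``multi_arm="most_intensive"`` instead keeps the largest-loss arm
    at programme end).  The sampling variance of a difference is
    ``sd_i²/n_i + sd_c²/n_c`` when both SDs are reported, else missing.

    For ``outcome="qol_raw"`` the per-arm QoL change is used, with
    lower-is-better scales sign-flipped so higher always means better; the
    result is in scale points (standardization to SMD lives downstream).

    Studies with no visit matching programme end are excluded with a warning.
    """
    out: list[DifferenceSeries] = []
    by_study: dict[str, list[ArmObservation]] = {}
    for a in corpus.arms:
        by_study.setdefault(a.study_id, []).append(a)

    for study_id in sorted(corpus.studies):
        meta = corpus.studies[study_id]
        arms = by_study.get(study_id, [])
        control = sorted(
            (a for a in arms if a.arm_role == "control"), key=lambda a: a.t_months
        )
        int_ids = sorted({a.arm_id for a in arms if a.arm_role == "intervention"})
        if not control or not int_ids:
            warnings.warn(f"study {study_id!r}: missing control or intervention arm; skipped")
            continue
        flip = -1.0 if (outcome != "weight_kg" and meta.qol_direction == "lower_better") else 1.0

        if multi_arm == "most_intensive" and len(int_ids) > 1:
            int_ids = [_most_intensive_arm(arms, int_ids, meta.programme_end_month)]

        int_by_arm = {
            aid: sorted((a for a in arms if a.arm_id == aid), key=lambda a: a.t_months)
            for aid in int_ids
        }
        points = []
        for cobs in control:
            c_mean, c_sd = _arm_outcome(cobs, outcome)
            if c_mean is None:
                continue
            means, sds, ns = [], [], []
            for aid in int_ids:
                seq = int_by_arm[aid]
                j = _match_time([a.t_months for a in seq], cobs.t_months)
                if j is None:
                    continue
                m, s = _arm_outcome(seq[j], outcome)
                if m is None:
                    continue
                means.append(m)
                sds.append(s)
                ns.append(seq[j].n_analyzed)
            if not means:
                continue
            w = np.asarray(ns, dtype=float)
            pooled_mean = float(np.average(means, weights=w))
            # variance of the n-weighted mean of arms, plus the control part
            if all(s is not None for s in sds) and c_sd is not None:
                var_int = float(np.sum((w / w.sum()) ** 2 * np.array(sds) ** 2 / w))
                var = var_int + c_sd**2 / cobs.n_analyzed
            else:
                var = None
            diff = flip * (pooled_mean - c_mean)
            t_rel = cobs.t_months - meta.programme_end_month
            points.append((t_rel, diff, var, int(w.sum()) + cobs.n_analyzed))

        if not points:
            # study reports nothing for this outcome (e.g. no QoL rows)
            continue
        i0 = _match_time([p[0] for p in points], 0.0)
        if i0 is None:
            warnings.warn(
                f"study {study_id!r}: no visit matches programme end "
                f"(month {meta.programme_end_month}); excluded"
            )
            continue
        # snap the matched visit to exactly t=0 and keep only t >= 0
        points[i0] = (0.0, *points[i0][1:])
        points = sorted((p for p in points if p[0] >= 0.0), key=lambda p: p[0])
        out.append(
            DifferenceSeries(
                study_id=study_id,
                outcome="weight_kg" if outcome == "weight_kg" else "qol_raw",
                points=tuple(points),
                max_followup_months=meta.max_followup_months,
            )
        )
    return out


def _most_intensive_arm(arms, int_ids, programme_end_month) -> str:
    """Arm with the largest weight loss at programme end (ties: first id)."""
    best, best_loss = int_ids[0], np.inf
    for aid in int_ids:
        seq = [a for a in arms if a.arm_id == aid]
        j = _match_time([a.t_months for a in seq], programme_end_month)
        if j is None:
            continue
        v = seq[j].mean_change_kg
        if v < best_loss:
            best, best_loss = aid, v
    return best


def filter_regain_eligible(series_list: Iterable[DifferenceSeries]) -> list[DifferenceSeries]:
    """Keep studies suitable for regain synthesis.

    Retained iff the intervention had lost weight relative to control at
    programme end (difference < 0 at t = 0), at least one post-programme
    point exists, and total follow-up is at least 12 months from baseline.
    Idempotent by construction.
    """
    kept = []
    for s in series_list:
        try:
            d0 = s.at_programme_end()
        except IntegrityError:
            continue
        has_post = any(t > 0 for t, *_ in s.points)
        long_enough = (
            not np.isnan(s.max_followup_months) and s.max_followup_months >= 12.0
        )
        if d0 < 0 and has_post and long_enough:
            kept.append(s)
    return kept


def filter_by_rob(corpus: Corpus, exclude: frozenset | set = frozenset({"high"})) -> Corpus:
    """Drop studies whose overall risk-of-bias rating is in ``exclude``."""
    keep = {sid for sid, m in corpus.studies.items() if m.rob_overall not in exclude}
    return Corpus(
        arms=[a for a in corpus.arms if a.study_id in keep],
        studies={sid: m for sid, m in corpus.studies.items() if sid in keep},
    )
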