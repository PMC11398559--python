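"""Daily Clinical Feature Scale (CFS) scoring from raw vital-sign streams.

The CFS is the severity half of the PSH Assessment Measure (PSH-AM), the
standard bedside instrument for paroxysmal sympathetic hyperactivity after
acquired brain injury.  Six categories — heart rate, systolic blood pressure,
respiratory rate, temperature, sweating and posturing — are each scored 0-3
per day, giving a daily total of 0-18.  The four physiologic categories are
scored from the *highest* value observed in each 24-hour window after
admission; sweating and posturing are scored from daily clinical-note
mentions (any mention -> 2, otherwise 0, since note text rarely grades
severity).

Day 0 (the first 24 h, resuscitation and stabilization) is excluded from
trajectory construction; the analysis series is the 13 daily totals for
days 1-13.

This module also tallies the Diagnosis Likelihood Tool (DLT), the 11-item
binary checklist half of the PSH-AM, from pre-adjudicated indicator booleans.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

VITAL_CATEGORIES: tuple[str, ...] = ("HR", "SBP", "RR", "TEMP")
SYMPTOM_CATEGORIES: tuple[str, ...] = ("SWEATING", "POSTURING")
ALL_CATEGORIES: tuple[str, ...] = VITAL_CATEGORIES + SYMPTOM_CATEGORIES

#: CFS score given to sweating/posturing for any clinical-note mention.
SYMPTOM_MENTION_SCORE = 2

#: Analysis trajectory covers days 1..13 (day 0 excluded).
TRAJECTORY_DAYS = 13

#: Names of the 11 binary DLT indicators (configurable; count is contractual).
DLT_INDICATOR_NAMES: tuple[str, ...] = (
    "simultaneity_of_features",
    "persistence_3_days",
    "persistence_14_days",
    "episode_frequency_2_per_day",
    "medication_requirement",
    "absence_of_parasympathetic_features",
    "absence_of_other_presumed_cause",
    "features_despite_treating_other_causes",
    "no_alternative_explanation",
    "antecedent_brain_injury",
    "paroxysmal_nature",
)


class InsufficientDataError(ValueError):
    """Raised when a patient has too few scored days to form a trajectory."""


@dataclass(frozen=True)
class CategoryRubric:
    """Cutpoints mapping a vital-sign value to a 0-3 severity band.

    Bands are left-closed on each cutpoint: ``value >= cutpoints[i]`` places
    the value in band ``i + 1``.
    """

    category: str
    cutpoints: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.cutpoints) != 3:
            raise ValueError(f"rubric for {self.category!r} needs exactly 3 cutpoints")
        c = self.cutpoints
        if not (c[0] < c[1] < c[2]):
            raise ValueError(f"cutpoints for {self.category!r} must be strictly increasing: {c}")

    def score(self, value: float) -> int:
        if not value > 0:
            raise ValueError(f"{self.category} value must be positive, got {value}")
        # number of cutpoints <= value == band index (left-closed convention)
        return int(np.searchsorted(self.cutpoints, value, side="right"))


#: Default rubrics from the PSH-AM instrument (overridable via config).
DEFAULT_RUBRICS: dict[str, CategoryRubric] = {
    "HR": CategoryRubric("HR", (100.0, 120.0, 140.0)),
    "SBP": CategoryRubric("SBP", (140.0, 160.0, 180.0)),
    "RR": CategoryRubric("RR", (18.0, 24.0, 30.0)),
    "TEMP": CategoryRubric("TEMP", (37.0, 38.0, 39.0)),
}


def load_rubrics(path: str) -> dict[str, CategoryRubric]:
    """Load category cutpoints from a YAML file ``{HR: [100, 120, 140], ...}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    rubrics = dict(DEFAULT_RUBRICS)
    for cat, cuts in (raw or {}).items():
        cat = str(cat).upper()
        if cat not in VITAL_CATEGORIES:
            raise ValueError(f"unknown rubric category {cat!r}")
        rubrics[cat] = CategoryRubric(cat, tuple(float(c) for c in cuts))
    return rubrics


@dataclass(frozen=True)
class SymptomDayFlags:
    """Pre-extracted note flags for one patient-day (at most one per day)."""

    patient_id: str
    day_index: int
    sweating_mentioned: bool = False
    posturing_mentioned: bool = False


@dataclass(frozen=True)
class DailyCFS:
    """Six category sub-scores and their total for one patient-day."""

    patient_id: str
    day_index: int
    sub_scores: Mapping[str, int]
    total: int
    missing_categories: frozenset[str]

    def __post_init__(self) -> None:
        if set(self.sub_scores) != set(ALL_CATEGORIES):
            raise ValueError("sub_scores must cover all six CFS categories")
        if self.total != sum(self.sub_scores.values()):
            raise ValueError("total must equal the sum of sub-scores")


@dataclass(frozen=True)
class CFSTrajectory:
    """Thirteen daily CFS totals (days 1-13) for one patient."""

    patient_id: str
    values: tuple[float, ...]
    imputed_days: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if len(self.values) != TRAJECTORY_DAYS:
            raise ValueError(f"trajectory must have exactly {TRAJECTORY_DAYS} values")
        if any(not (0 <= v <= 18) for v in self.values):
            raise ValueError("trajectory values must lie in [0, 18]")


@dataclass(frozen=True)
class DLTRecord:
    """The 11 binary DLT indicators and their tally for one patient."""

    patient_id: str
    indicators: Mapping[str, bool]
    tally: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "tally", dlt_tally(self.indicators.values()))


def score_vital_category(value: float, rubric: CategoryRubric) -> int:
    """Score one vital-sign value 0-3 under a category rubric."""
    return rubric.score(value)


def score_symptom_category(mentioned: bool) -> int:
    """Score sweating/posturing from a note flag: any mention -> 2, else 0."""
    return SYMPTOM_MENTION_SCORE if mentioned else 0


def dlt_tally(indicators: Iterable[bool]) -> int:
    """Count true indicators among exactly 11 DLT booleans."""
    vals = [bool(v) for v in indicators]
    if len(vals) != 11:
        raise ValueError(f"DLT requires exactly 11 indicators, got {len(vals)}")
    return sum(vals)


def _parse_timestamps(series: pd.Series) -> pd.Series:
    out = pd.to_datetime(series, errors="coerce", format="ISO8601")
    bad = out.isna() & series.notna()
    if bad.any():
        i = bad.idxmax()
        raise ValueError(f"unparseable timestamp {series.loc[i]!r} at record {i}")
    return out


def window_vitals(
    samples: pd.DataFrame,
    admission_time: Mapping[str, pd.Timestamp] | pd.Timestamp,
    n_days: int = 14,
) -> dict[str, dict[int, dict[str, float]]]:
    """Reduce a vital-sign stream to per-day, per-parameter maxima.

    Day ``d`` covers the half-open window ``[admission + d*24h,
    admission + (d+1)*24h)``.  Samples before admission are dropped with a
    logged warning count; samples at or beyond day ``n_days`` are ignored.

    Parameters
    ----------
    samples
        Long-format frame with columns ``patient_id, timestamp, parameter,
        value``.  Timestamps may be strings (ISO-8601) or datetimes.
    admission_time
        Either a single timestamp applied to all patients or a mapping
        ``patient_id -> timestamp``.

    Returns
    -------
    dict
        ``{patient_id: {day_index: {parameter: max_value}}}``.  A parameter
        with no sample in a window is absent from that day's dict.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    if samples.empty:
        return {}
    df = samples.copy()
    ts = df["timestamp"]
    if not np.issubdtype(ts.dtype, np.datetime64):
        df["timestamp"] = _parse_timestamps(ts)
    bad_param = ~df["parameter"].isin(VITAL_CATEGORIES)
    if bad_param.any():
        raise ValueError(f"unknown vital parameter(s): {sorted(df.loc[bad_param, 'parameter'].unique())}")
    if (df["value"] <= 0).any():
        raise ValueError("vital-sign values must be positive")

    if isinstance(admission_time, pd.Timestamp):
        adm = pd.Series(admission_time, index=df["patient_id"].unique())
    else:
        adm = pd.Series(dict(admission_time))
    missing_adm = set(df["patient_id"].unique()) - set(adm.index)
    if missing_adm:
        raise KeyError(f"no admission_time for patient(s): {sorted(missing_adm)}")

    rel = df["timestamp"] - df["patient_id"].map(adm)
    day = (rel / pd.Timedelta(hours=24)).to_numpy()
    day_idx = np.floor(day).astype(int)
    early = day_idx < 0
    if early.any():
        logger.warning("dropped %d vital sample(s) recorded before admission", int(early.sum()))
    keep = (~early) & (day_idx < n_days)
    df = df.loc[keep].assign(day_index=day_idx[keep])

    out: dict[str, dict[int, dict[str, float]]] = {}
    grouped = df.groupby(["patient_id", "day_index", "parameter"], sort=True)["value"].max()
    for (pid, d, param), vmax in grouped.items():
        out.setdefault(pid, {}).setdefault(int(d), {})[param] = float(vmax)
    return out


def daily_cfs(
    day_maxima: Mapping[str, float],
    flags: SymptomDayFlags | None,
    rubrics: Mapping[str, CategoryRubric] | None = None,
    *,
    patient_id: str = "",
    day_index: int = 0,
    missing_policy: str = "zero",
) -> DailyCFS:
    """Score one patient-day from daily vital maxima and note flags.

    A vital category with no data that day is scored per ``missing_policy``
    (default ``"zero"``: sub-score 0, recorded in ``missing_categories``).
    Missingness is a flagged state, never an error.
    """
    if missing_policy != "zero":
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    rubrics = DEFAULT_RUBRICS if rubrics is None else rubrics
    missing = set(VITAL_CATEGORIES) - set(rubrics)
    if missing:
        raise ValueError(f"rubrics missing for categories: {sorted(missing)}")

    sub: dict[str, int] = {}
    absent: set[str] = set()
    for cat in VITAL_CATEGORIES:
        if cat in day_maxima and day_maxima[cat] is not None:
            sub[cat] = score_vital_category(day_maxima[cat], rubrics[cat])
        else:
            sub[cat] = 0
            absent.add(cat)
    if flags is None:
        sub["SWEATING"] = 0
        sub["POSTURING"] = 0
    else:
        sub["SWEATING"] = score_symptom_category(flags.sweating_mentioned)
        sub["POSTURING"] = score_symptom_category(flags.posturing_mentioned)
    return DailyCFS(
        patient_id=patient_id or (flags.patient_id if flags else ""),
        day_index=day_index if flags is None else flags.day_index,
        sub_scores=sub,
        total=sum(sub.values()),
        missing_categories=frozenset(absent),
    )


def build_trajectory(daily_scores: Sequence[DailyCFS]) -> CFSTrajectory:
    """Assemble the 13-day analysis trajectory (days 1-13) for one patient.

    Day 0 records are dropped.  Wholly missing interior days are filled by
    linear interpolation between the nearest scored neighbours; missing
    boundary days carry the nearest scored value.  Filled day indices are
    recorded in ``imputed_days``.

    Raises
    ------
    InsufficientDataError
        If fewer than two of days 1-13 were scored.
    """
    if not daily_scores:
        raise InsufficientDataError("no scored days")
    pid = daily_scores[0].patient_id
    scored = {s.day_index: s.total for s in daily_scores if 1 <= s.day_index <= TRAJECTORY_DAYS}
    if len(scored) < 2:
        raise InsufficientDataError(
            f"patient {pid!r}: only {len(scored)} scored day(s) among days 1-{TRAJECTORY_DAYS}"
        )
    days = np.array(sorted(scored))
    vals = np.array([scored[d] for d in days], dtype=float)
    full_days = np.arange(1, TRAJECTORY_DAYS + 1)
    # np.interp does linear interpolation inside and nearest-value carry outside
    filled = np.interp(full_days, days, vals)
    imputed = frozenset(int(d) for d in full_days if int(d) not in scored)
    if imputed:
        logger.info("patient %r: imputed day(s) %s", pid, sorted(imputed))
    return CFSTrajectory(patient_id=pid, values=tuple(filled), imputed_days=imputed)


def score_cohort(
    vitals: pd.DataFrame,
    flags: pd.DataFrame | None = None,
    rubrics: Mapping[str, CategoryRubric] | None = None,
    admission_time: Mapping[str, pd.Timestamp] | None = None,
    n_days: int = 14,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Score a whole cohort: vitals + note flags -> daily table + trajectories.

    If ``admission_time`` is omitted, each patient's earliest vital timestamp
    is used (the synthetic generator pins a sample at the admission instant,
    making this exact on generated cohorts).

    Returns
    -------
    daily : DataFrame
        Columns ``patient_id, day_index, hr, sbp, rr, temp, sweating,
        posturing, total, missing``.
    matrix : DataFrame
        One row per included patient: ``patient_id, day1..day13, imputed``.
    excluded : dict
        ``patient_id -> reason`` for patients without a usable trajectory.
    """
    rubrics = DEFAULT_RUBRICS if rubrics is None else rubrics
    vit = vitals.copy()
    if not vit.empty and not np.issubdtype(vit["timestamp"].dtype, np.datetime64):
        vit["timestamp"] = _parse_timestamps(vit["timestamp"])
    if admission_time is None:
        admission_time = vit.groupby("patient_id")["timestamp"].min().to_dict() if not vit.empty else {}

    flag_map: dict[tuple[str, int], SymptomDayFlags] = {}
    if flags is not None and not flags.empty:
        for row in flags.itertuples(index=False):
            key = (str(row.patient_id), int(row.day_index))
            if key in flag_map:
                raise ValueError(f"duplicate symptom flags for patient-day {key}")
            flag_map[key] = SymptomDayFlags(
                patient_id=key[0],
                day_index=key[1],
                sweating_mentioned=bool(int(getattr(row, "sweating"))),
                posturing_mentioned=bool(int(getattr(row, "posturing"))),
            )

    windows = window_vitals(vit, admission_time, n_days=n_days) if not vit.empty else {}
    patients = sorted(set(windows) | {pid for pid, _ in flag_map})

    daily_rows = []
    matrix_rows = []
    excluded: dict[str, str] = {}
    for pid in patients:
        per_day: list[DailyCFS] = []
        pdays = windows.get(pid, {})
        day_indices = sorted(set(pdays) | {d for p, d in flag_map if p == pid})
        for d in day_indices:
            rec = daily_cfs(
                pdays.get(d, {}),
                flag_map.get((pid, d)),
                rubrics,
                patient_id=pid,
                day_index=d,
            )
            per_day.append(rec)
            daily_rows.append(
                {
                    "patient_id": pid,
                    "day_index": d,
                    "hr": rec.sub_scores["HR"],
                    "sbp": rec.sub_scores["SBP"],
                    "rr": rec.sub_scores["RR"],
                    "temp": rec.sub_scores["TEMP"],
                    "sweating": rec.sub_scores["SWEATING"],
                    "posturing": rec.sub_scores["POSTURING"],
                    "total": rec.total,
                    "missing": ";".join(sorted(rec.missing_categories)),
                }
            )
        try:
            traj = build_trajectory(per_day)
        except InsufficientDataError as exc:
            excluded[pid] = str(exc)
            logger.warning("excluding %r: %s", pid, exc)
            continue
        row: dict[str, object] = {"patient_id": pid}
        row.update({f"day{d}": traj.values[d - 1] for d in range(1, TRAJECTORY_DAYS + 1)})
        row["imputed"] = ";".join(str(d) for d in sorted(traj.imputed_days))
        matrix_rows.append(row)

    daily_cols = [
        "patient_id", "day_index", "hr", "sbp", "rr", "temp",
        "sweating", "posturing", "total", "missing",
    ]
    matrix_cols = ["patient_id"] + [f"day{d}" for d in range(1, TRAJECTORY_DAYS + 1)] + ["imputed"]
    daily = pd.DataFrame(daily_rows, columns=daily_cols)
    matrix = pd.DataFrame(matrix_rows, columns=matrix_cols)
    return daily, matrix, excluded
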