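"""Synthetic TBI cohort generator with known trajectory-group structure.

Emits everything the pipeline consumes — a raw vital-sign stream, daily
note flags, admission covariates, hospital outcomes — plus the ground-truth
group label of every patient, so that scoring, clustering, association and
regression stages can all be exercised and validated without any protected
health data.

The generative model is deliberately simple and group-first:

1. each patient is assigned to one of four latent trajectory archetypes
   (persistently low / decreasing / increasing / persistently high mean
   daily CFS) with configurable mixing proportions;
2. a daily CFS *total* is drawn around the archetype's mean curve
   (Gaussian noise on the total, then rounded and clipped);
3. the total is split across the six CFS categories by a deterministic
   greedy allocation, and raw vital-sign samples are synthesized whose
   24-hour maxima fall exactly in the allocated severity bands (so scoring
   the generated stream reproduces the generated sub-scores exactly);
4. covariates (age, motor GCS, ...) and outcomes (PSH diagnosis, DLT, ICU
   length of stay, ventilation days, ...) are drawn conditional on the
   latent group, with defaults mirroring the group-level summary statistics
   of the cohort this pipeline was designed around.

Because symptom categories score only 0 or 2 under the any-mention note
rule, achievable daily totals are capped at 16 (4x3 vitals + 2 + 2); drawn
totals are clipped into [0, 16] before allocation.  The default archetype
curves peak at 10, so the cap is essentially never active at default noise.

What this generator does *not* emulate: intra-day paroxysm dynamics,
circadian rhythm, informative missingness, or covariate-first causal
structure.  Passing recovery tests on these cohorts demonstrates that the
pipeline's machinery is correct, not that real EHR data would yield the
same groups.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .scoring import (
    ALL_CATEGORIES,
    DEFAULT_RUBRICS,
    SYMPTOM_CATEGORIES,
    VITAL_CATEGORIES,
    CategoryRubric,
    SymptomDayFlags,
)

__all__ = [
    "ArchetypeSpec",
    "CohortConfig",
    "SyntheticCohort",
    "make_default_archetypes",
    "simulate_vitals_for_target_cfs",
    "simulate_trajectories",
    "simulate_covariates",
    "simulate_outcomes",
    "generate_cohort",
    "write_cohort",
]

#: Plausible physiologic floors used when sampling below the first cutpoint.
BAND_FLOORS = {"HR": 55.0, "SBP": 90.0, "RR": 8.0, "TEMP": 36.0}
#: Physiologic caps applied to the top-band exponential tail.
BAND_CAPS = {"HR": 220.0, "SBP": 260.0, "RR": 60.0, "TEMP": 43.0}


@dataclass(frozen=True)
class ArchetypeSpec:
    """One latent trajectory archetype: a 13-day mean CFS curve plus noise."""

    name: str
    mean_curve: tuple[float, ...]
    sd_noise: float = 1.5

    def __post_init__(self) -> None:
        if len(self.mean_curve) != 13:
            raise ValueError("mean_curve must have length 13")
        if any(not (0 <= v <= 18) for v in self.mean_curve):
            raise ValueError("mean_curve values must lie in [0, 18]")
        if self.sd_noise < 0:
            raise ValueError("sd_noise must be non-negative")


def make_default_archetypes(sd_noise: float = 1.5) -> list[ArchetypeSpec]:
    """The four default archetypes: flat-low, decreasing, increasing, flat-high.

    Curve levels are free constants chosen to be mutually well separated
    (pairwise DTW distance between mean curves exceeds five times the noise
    SD), with qualitative shapes matching the four clinical trajectory
    phenotypes: persistently low (~2), high-start decreasing (8 -> 3),
    low-start increasing (3 -> 9), persistently high (~10).
    """
    return [
        ArchetypeSpec("persistently_low", (2.0,) * 13, sd_noise),
        ArchetypeSpec("decreasing", tuple(float(v) for v in np.linspace(8.0, 3.0, 13)), sd_noise),
        ArchetypeSpec("increasing", tuple(float(v) for v in np.linspace(3.0, 9.0, 13)), sd_noise),
        ArchetypeSpec("persistently_high", (10.0,) * 13, sd_noise),
    ]


@dataclass(frozen=True)
class CohortConfig:
    """All knobs of the synthetic cohort, with defaults mirroring the study
    conditions (group proportions, ages, motor GCS, PSH rates, DLT, LOS)."""

    n_patients: int = 221
    group_proportions: tuple[float, ...] = (0.14, 0.33, 0.29, 0.24)
    sd_noise: float = 1.5
    archetypes: tuple[ArchetypeSpec, ...] | None = None

    # covariates (per-group where tuple-valued; group order = archetype order)
    age_means: tuple[float, ...] = (52.0, 48.0, 40.0, 38.0)
    age_sd: float = 18.0
    age_bounds: tuple[float, float] = (18.0, 95.0)
    mgcs_centers: tuple[float, ...] = (4.0, 5.0, 3.0, 2.0)
    mgcs_sd: float = 2.5
    bmi_mean: float = 26.0
    bmi_sd: float = 6.0
    bmi_min: float = 12.0
    iss_mean: float = 26.0
    iss_sd: float = 8.0
    male_fraction: float = 0.79
    icp_monitor_fraction: float = 0.54

    # outcomes
    psh_probs: tuple[float, ...] = (0.26, 0.38, 0.57, 0.65)
    dlt_probs: tuple[float, ...] = (0.18, 0.36, 0.60, 0.68)
    icu_los_means: tuple[float, ...] = (17.8, 17.5, 21.1, 21.5)
    vent_days_means: tuple[float, ...] = (12.7, 11.3, 15.0, 15.3)
    hospital_los_means: tuple[float, ...] = (27.6, 27.0, 29.7, 31.3)
    los_sigma: float = 0.5
    survival_prob: float = 0.94
    following_commands_prob: float = 0.72

    n_days: int = 14
    admission_start: str = "2016-01-01T00:00:00"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        arch = self.archetypes or tuple(make_default_archetypes(self.sd_noise))
        object.__setattr__(self, "archetypes", tuple(arch))
        G = len(self.archetypes)
        props = np.asarray(self.group_proportions, dtype=float)
        if len(props) != G:
            raise ValueError("group_proportions must match the number of archetypes")
        if not np.isclose(props.sum(), 1.0):
            raise ValueError("group_proportions must sum to 1")
        for name in ("age_means", "mgcs_centers", "psh_probs", "dlt_probs",
                     "icu_los_means", "vent_days_means", "hospital_los_means"):
            if len(getattr(self, name)) != G:
                raise ValueError(f"{name} must have one entry per archetype")
        for p in (*self.psh_probs, *self.dlt_probs, self.survival_prob,
                  self.male_fraction, self.icp_monitor_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_groups(self) -> int:
        return len(self.archetypes)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["archetypes"] = [
            {
                "name": str(a["name"]),
                "mean_curve": [float(v) for v in a["mean_curve"]],
                "sd_noise": float(a["sd_noise"]),
            }
            for a in d["archetypes"]
        ]
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "archetypes" in raw and raw["archetypes"] is not None:
            raw["archetypes"] = tuple(
                ArchetypeSpec(a["name"], tuple(a["mean_curve"]), a.get("sd_noise", 1.5))
                for a in raw["archetypes"]
            )
        tuple_fields = {
            f.name for f in dataclasses.fields(cls)
            if f.name != "archetypes" and isinstance(getattr(cls, f.name, None), tuple)
        }
        kwargs = {
            k: tuple(v) if k in tuple_fields and isinstance(v, list) else v
            for k, v in raw.items()
        }
        return cls(**kwargs)


@dataclass(frozen=True)
class SyntheticCohort:
    """A complete generated cohort plus its ground truth."""

    vitals: pd.DataFrame
    flags: pd.DataFrame
    covariates: pd.DataFrame
    covariate_types: pd.DataFrame
    outcomes: pd.DataFrame
    true_labels: pd.Series
    admissions: pd.DataFrame
    config: CohortConfig


def allocate_total(total: int) -> dict[str, int]:
    """Deterministically split a daily CFS total across the six categories.

    Vitals are filled round-robin (HR, SBP, RR, TEMP) up to 3 points each;
    any remainder goes to the symptoms in steps of 2 (sweating first).
    Totals are clipped into the achievable range [0, 16].
    """
    t = int(np.clip(total, 0, 16))
    sub = {c: 0 for c in ALL_CATEGORIES}
    if t > 14:
        symptoms, vitals = 4, t - 4
    elif t > 12:
        symptoms, vitals = 2, t - 2
    else:
        symptoms, vitals = 0, t
    base, extra = divmod(vitals, 4)
    for i, cat in enumerate(VITAL_CATEGORIES):
        sub[cat] = base + (1 if i < extra else 0)
    sub["SWEATING"] = 2 if symptoms >= 2 else 0
    sub["POSTURING"] = 2 if symptoms >= 4 else 0
    return sub


def _sample_in_band(cat: str, band: int, rubric: CategoryRubric, rng: np.random.Generator) -> float:
    cuts = rubric.cutpoints
    floor, cap = BAND_FLOORS[cat], BAND_CAPS[cat]
    if floor >= cuts[0] or cap <= cuts[2]:
        raise ValueError(f"target band unreachable for {cat} under rubric {cuts}")
    if band < 3:
        low = floor if band == 0 else cuts[band - 1]
        high = cuts[band]
        v = float(rng.uniform(low, high))
        return min(v, np.nextafter(high, low))
    return float(min(cuts[2] + rng.exponential((cap - cuts[2]) / 3.0), cap))


def simulate_vitals_for_target_cfs(
    target_sub_scores: dict[str, int],
    rubrics: dict[str, CategoryRubric] | None,
    rng: np.random.Generator,
    *,
    patient_id: str = "p0",
    day_index: int = 0,
    day_start: pd.Timestamp | None = None,
    n_samples_per_param: int = 3,
    pin_first_sample: bool = False,
) -> tuple[list[dict], SymptomDayFlags]:
    """Inverse scoring: emit raw samples whose daily maxima hit target bands.

    For each vital category at least three samples are placed inside the
    24-hour window; the window maximum lands strictly inside the value band
    of the target sub-score (top band: band start plus an exponential tail
    clipped at a physiologic cap).  Symptom flags are set iff the target
    symptom sub-score is 2.  Scoring the emitted stream round-trips exactly
    to the target sub-scores.
    """
    rubrics = DEFAULT_RUBRICS if rubrics is None else rubrics
    day_start = pd.Timestamp("2016-01-01") if day_start is None else day_start
    for cat, s in target_sub_scores.items():
        if cat in SYMPTOM_CATEGORIES and s not in (0, 2):
            raise ValueError(f"symptom target for {cat} must be 0 or 2, got {s}")
        if cat in VITAL_CATEGORIES and s not in (0, 1, 2, 3):
            raise ValueError(f"vital target for {cat} must be in 0..3, got {s}")
    rows: list[dict] = []
    for cat in VITAL_CATEGORIES:
        band = int(target_sub_scores.get(cat, 0))
        vmax = _sample_in_band(cat, band, rubrics[cat], rng)
        others = rng.uniform(BAND_FLOORS[cat], vmax, size=max(n_samples_per_param - 1, 2))
        values = np.concatenate([[vmax], others])
        offsets = np.sort(rng.uniform(0.0, 24.0, size=len(values)))
        rng.shuffle(values)
        if pin_first_sample and cat == "HR":
            offsets[0] = 0.0
        for off, val in zip(offsets, values):
            rows.append(
                {
                    "patient_id": patient_id,
                    "timestamp": day_start + pd.Timedelta(hours=float(off)),
                    "parameter": cat,
                    # full float precision so scoring the CSV round-trips exactly
                    "value": float(val),
                }
            )
    flags = SymptomDayFlags(
        patient_id=patient_id,
        day_index=day_index,
        sweating_mentioned=target_sub_scores.get("SWEATING", 0) == 2,
        posturing_mentioned=target_sub_scores.get("POSTURING", 0) == 2,
    )
    return rows, flags


def simulate_trajectories(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[list[dict[str, int]]]]:
    """Draw latent labels, daily totals and category allocations.

    Returns ``(labels, totals, allocations)`` where ``totals`` has shape
    ``(n_patients, n_days)`` (day 0 included; its target reuses the day-1
    curve value) and ``allocations[p][d]`` maps categories to sub-scores.
    Totals are the *realized* allocation sums, so downstream round-trips are
    exact.
    """
    N, D = config.n_patients, config.n_days
    labels = rng.choice(config.n_groups, size=N, p=np.asarray(config.group_proportions))
    totals = np.zeros((N, D), dtype=int)
    allocations: list[list[dict[str, int]]] = []
    for p in range(N):
        arch = config.archetypes[labels[p]]
        per_day = []
        for d in range(D):
            mean = arch.mean_curve[min(max(d - 1, 0), 12)]
            t = int(np.clip(np.rint(mean + rng.normal(0.0, arch.sd_noise)), 0, 18))
            sub = allocate_total(t)
            totals[p, d] = sum(sub.values())
            per_day.append(sub)
        allocations.append(per_day)
    return labels, totals, allocations


def _truncnorm(rng: np.random.Generator, mean: float, sd: float,
               low: float, high: float, size: int) -> np.ndarray:
    """Truncated normal by rejection (bounds are always >1 SD wide here)."""
    out = rng.normal(mean, sd, size)
    bad = (out < low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < low) | (out > high)
    return out


def simulate_covariates(
    true_labels: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Admission covariates conditional on latent group.

    Only age and motor GCS depend on the group by default; BMI, ISS, head
    AIS, sex and ICP-monitor placement are group-independent noise
    covariates (so predictor-recovery tests have a known truth).
    Returns ``(covariates, covariate_types)``.
    """
    N = len(true_labels)
    g = np.asarray(true_labels, dtype=int) if N else np.array([], dtype=int)
    age = np.empty(N)
    for gi in range(config.n_groups):
        mask = g == gi
        age[mask] = _truncnorm(
            rng, config.age_means[gi], config.age_sd,
            config.age_bounds[0], config.age_bounds[1], int(mask.sum()),
        )
    centers = np.asarray(config.mgcs_centers)[g] if N else np.array([])
    mgcs = np.clip(np.rint(rng.normal(centers, config.mgcs_sd)), 1, 6).astype(int)
    df = pd.DataFrame(
        {
            "patient_id": [f"p{i:04d}" for i in range(N)],
            "age": np.round(age, 1),
            "mgcs": mgcs,
            "bmi": np.round(_truncnorm(rng, config.bmi_mean, config.bmi_sd, config.bmi_min, np.inf, N), 1),
            "iss": np.clip(np.rint(rng.normal(config.iss_mean, config.iss_sd, N)), 1, 75).astype(int),
            "head_ais": rng.choice([3, 4, 5], size=N, p=[0.3, 0.45, 0.25]),
            "sex": np.where(rng.random(N) < config.male_fraction, "male", "female"),
            "icp_monitor": np.where(rng.random(N) < config.icp_monitor_fraction, "yes", "no"),
        }
    )
    types = pd.DataFrame(
        {
            "feature": ["age", "mgcs", "bmi", "iss", "head_ais", "sex", "icp_monitor"],
            "type": ["continuous", "continuous", "continuous", "continuous",
                     "continuous", "categorical", "categorical"],
        }
    )
    return df, types


def simulate_outcomes(
    true_labels: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Hospital outcomes conditional on latent group.

    PSH diagnosis is Bernoulli with a group-specific rate; DLT is
    Binomial(11, q_g) with q increasing in group severity; ICU/hospital LOS
    and ventilation days are group-shifted lognormals.  Discharge GCS
    components and survival are drawn independent of group (no association
    was expected for them).
    """
    N = len(true_labels)
    g = np.asarray(true_labels, dtype=int) if N else np.array([], dtype=int)

    def lognorm(means: tuple[float, ...]) -> np.ndarray:
        if N == 0:
            return np.array([])
        mu = np.log(np.asarray(means)[g]) - config.los_sigma**2 / 2
        return np.round(np.exp(rng.normal(mu, config.los_sigma)), 1)

    eye = rng.choice([1, 2, 3, 4], size=N, p=[0.05, 0.05, 0.10, 0.80])
    motor = rng.choice([1, 2, 3, 4, 5, 6], size=N, p=[0.03, 0.02, 0.05, 0.10, 0.20, 0.60])
    verbal = rng.choice([1, 2, 3, 4, 5], size=N, p=[0.25, 0.10, 0.15, 0.25, 0.25])
    return pd.DataFrame(
        {
            "patient_id": [f"p{i:04d}" for i in range(N)],
            "psh_case": (rng.random(N) < np.asarray(config.psh_probs)[g]).astype(int) if N else [],
            "dlt": rng.binomial(11, np.asarray(config.dlt_probs)[g]) if N else [],
            "survived": (rng.random(N) < config.survival_prob).astype(int),
            "gcs_eye": eye,
            "gcs_motor": motor,
            "gcs_verbal": verbal,
            "gcs_total": eye + motor + verbal,
            "following_commands": (rng.random(N) < config.following_commands_prob).astype(int),
            "hospital_los": lognorm(config.hospital_los_means),
            "icu_los": lognorm(config.icu_los_means),
            "vent_days": lognorm(config.vent_days_means),
        }
    )


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate a complete cohort deterministically from ``config.seed``."""
    config = CohortConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    labels, _totals, allocations = simulate_trajectories(config, rng)
    admission0 = pd.Timestamp(config.admission_start)

    vital_rows: list[dict] = []
    flag_rows: list[dict] = []
    adm_rows: list[dict] = []
    for p in range(config.n_patients):
        pid = f"p{p:04d}"
        admission = admission0 + pd.Timedelta(hours=6 * p)
        adm_rows.append({"patient_id": pid, "admission_time": admission})
        for d in range(config.n_days):
            rows, flags = simulate_vitals_for_target_cfs(
                allocations[p][d],
                DEFAULT_RUBRICS,
                rng,
                patient_id=pid,
                day_index=d,
                day_start=admission + pd.Timedelta(hours=24 * d),
                pin_first_sample=(d == 0),
            )
            vital_rows.extend(rows)
            flag_rows.append(
                {
                    "patient_id": pid,
                    "day_index": d,
                    "sweating": int(flags.sweating_mentioned),
                    "posturing": int(flags.posturing_mentioned),
                }
            )

    covariates, cov_types = simulate_covariates(labels, config, rng)
    outcomes = simulate_outcomes(labels, config, rng)
    ids = [f"p{i:04d}" for i in range(config.n_patients)]
    return SyntheticCohort(
        vitals=pd.DataFrame(vital_rows, columns=["patient_id", "timestamp", "parameter", "value"]),
        flags=pd.DataFrame(flag_rows, columns=["patient_id", "day_index", "sweating", "posturing"]),
        covariates=covariates,
        covariate_types=cov_types,
        outcomes=outcomes,
        true_labels=pd.Series(labels, index=ids, name="group"),
        admissions=pd.DataFrame(adm_rows, columns=["patient_id", "admission_time"]),
        config=config,
    )


def write_cohort(cohort: SyntheticCohort, outdir: str) -> None:
    """Write the cohort to the pipeline's CSV formats under ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    vit = cohort.vitals.copy()
    if not vit.empty:
        vit["timestamp"] = vit["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    vit.to_csv(os.path.join(outdir, "vitals.csv"), index=False)
    cohort.flags.to_csv(os.path.join(outdir, "flags.csv"), index=False)
    cohort.covariates.to_csv(os.path.join(outdir, "covariates.csv"), index=False)
    cohort.covariate_types.to_csv(os.path.join(outdir, "covariate_types.csv"), index=False)
    cohort.outcomes.to_csv(os.path.join(outdir, "outcomes.csv"), index=False)
    truth = cohort.true_labels.rename_axis("patient_id").reset_index()
    truth.to_csv(os.path.join(outdir, "truth.csv"), index=False)
    adm = cohort.admissions.copy()
    if not adm.empty:
        adm["admission_time"] = adm["admission_time"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    adm.to_csv(os.path.join(outdir, "admissions.csv"), index=False)
    with open(os.path.join(outdir, "config.yaml"), "w") as fh:
        fh.write(cohort.config.to_yaml())
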