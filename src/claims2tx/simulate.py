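"""Synthetic claims + abstraction generator for pipeline validation.

Restricted registry-linked claims cannot be redistributed, so this module
fabricates matched (truth, multi-source claims, gold-standard abstraction)
datasets with the statistical structure the validation assumes:

* per-agent Bernoulli treatment prevalence with guideline-like cycle plans
  laid out at fixed cycle intervals after a diagnosis-relative start offset;
* weekday-only radiotherapy fraction sequences for standard /
  hypofractionated / accelerated partial-breast schedules, with optional
  mid-course interruptions and premature truncation;
* per-source claim noise: an episode is captured by a source with a
  configured sensitivity, captured episodes may drop individual dates, and
  false-positive episodes (short 1-2 date runs mimicking billing artifacts)
  are injected at a configured rate;
* abstraction-side incompleteness via an abstraction sensitivity switch and
  optional multiplicative dose noise.

All randomness flows from a single integer seed through fixed named
substreams, so a configuration reproduces byte-identical datasets on any
platform.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .codes import BIOLOGIC, CHEMO, ENDOCRINE, CodeMap, default_code_map
from .dose import (
    APBI,
    HYPOFRACTIONATED,
    MAX_TOTAL_GY,
    STANDARD,
    RegimenTable,
    cumulative_chemo_dose,
    default_regimen_table,
)
from .identify import MEDICAL, PHARMACY, ClaimRecord, PatientProfile

#: Gy per fraction actually delivered under each true schedule.
TRUE_GY_PER_FRACTION = {STANDARD: 2.0, HYPOFRACTIONATED: 2.66, APBI: 3.4}
_PLANNED_FRACTIONS = {STANDARD: (25, 28), HYPOFRACTIONATED: (15, 16), APBI: (10, 10)}

#: External-beam delivery codes the simulator bills RT fractions under.
_RT_EMIT_CODES = ("77412", "77413", "77414")
_RT_PLANNING_CODE = "77301"


class AgentPlan(BaseModel):
    modality: str = CHEMO
    prevalence: float = Field(ge=0.0, le=1.0)
    cycles: dict[int, float]  # distribution over cycle counts
    cycle_days: int = Field(default=21, gt=0)
    start_offset_days: tuple[int, int] = (75, 120)

    @field_validator("modality")
    @classmethod
    def _known_modality(cls, v: str) -> str:
        if v not in (CHEMO, ENDOCRINE, BIOLOGIC):
            raise ValueError(f"unknown modality {v!r}")
        return v

    @field_validator("cycles")
    @classmethod
    def _valid_distribution(cls, v: dict[int, float]) -> dict[int, float]:
        if not v or any(p < 0 for p in v.values()) or any(k <= 0 for k in v):
            raise ValueError("cycles must map positive counts to non-negative weights")
        total = sum(v.values())
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"cycle weights must sum to 1 (got {total})")
        return v


class SourcePlan(BaseModel):
    sensitivity: float = Field(ge=0.0, le=1.0)
    false_positive_rate: float = Field(default=0.0, ge=0.0, le=1.0)
    date_dropout: float = Field(default=0.0, ge=0.0, le=1.0)
    fp_episode_lengths: tuple[int, ...] = (1, 2)


class RadiotherapyPlan(BaseModel):
    prevalence: float = Field(default=0.55, ge=0.0, le=1.0)
    schedule_mix: dict[str, float] = {STANDARD: 0.6, HYPOFRACTIONATED: 0.3, APBI: 0.1}
    incompletion_probability: float = Field(default=0.15, ge=0.0, le=1.0)
    interruption_probability: float = Field(default=0.10, ge=0.0, le=1.0)
    interruption_gap_days: tuple[int, int] = (7, 21)
    start_offset_days: tuple[int, int] = (100, 220)

    @field_validator("schedule_mix")
    @classmethod
    def _valid_mix(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) - set(_PLANNED_FRACTIONS):
            raise ValueError(f"unknown schedules in mix: {sorted(set(v) - set(_PLANNED_FRACTIONS))}")
        if any(p < 0 for p in v.values()) or not np.isclose(sum(v.values()), 1.0, atol=1e-6):
            raise ValueError("schedule mix must be a probability distribution")
        return v


class CovariatePlan(BaseModel):
    age_mean: float = 52.0
    age_sd: float = 8.0
    age_range: tuple[float, float] = (25.0, 64.0)
    height_mean_cm: float = 162.0
    height_sd_cm: float = 7.0
    weight_mean_kg: float = 76.0
    weight_sd_kg: float = 15.0
    weight_range_kg: tuple[float, float] = (42.0, 140.0)
    serum_creatinine_mg_dl: float = 0.8


def _default_agents() -> dict[str, AgentPlan]:
    # Margins loosely echo the validation cohort's per-agent exposure shares.
    return {
        "carboplatin": AgentPlan(modality=CHEMO, prevalence=0.12, cycles={4: 0.3, 6: 0.7}),
        "cyclophosphamide": AgentPlan(modality=CHEMO, prevalence=0.42, cycles={4: 0.7, 6: 0.3}),
        "docetaxel": AgentPlan(modality=CHEMO, prevalence=0.32, cycles={4: 0.6, 6: 0.4}),
        "doxorubicin": AgentPlan(modality=CHEMO, prevalence=0.21, cycles={4: 0.9, 6: 0.1}),
        "paclitaxel": AgentPlan(modality=CHEMO, prevalence=0.18, cycles={4: 0.5, 6: 0.5}),
        "tamoxifen": AgentPlan(
            modality=ENDOCRINE, prevalence=0.34, cycles={6: 0.4, 8: 0.6},
            cycle_days=30, start_offset_days=(60, 120),
        ),
        "anastrozole": AgentPlan(
            modality=ENDOCRINE, prevalence=0.26, cycles={6: 0.4, 8: 0.6},
            cycle_days=30, start_offset_days=(60, 120),
        ),
        "letrozole": AgentPlan(
            modality=ENDOCRINE, prevalence=0.11, cycles={6: 0.4, 8: 0.6},
            cycle_days=30, start_offset_days=(60, 120),
        ),
        "trastuzumab": AgentPlan(
            modality=BIOLOGIC, prevalence=0.13, cycles={6: 0.5, 11: 0.5}
        ),
    }


def _default_sources() -> dict[str, SourcePlan]:
    return {
        "APCD": SourcePlan(sensitivity=0.89, false_positive_rate=0.05, date_dropout=0.05),
        "UCR_claims": SourcePlan(sensitivity=0.28, false_positive_rate=0.01),
        "EMR": SourcePlan(sensitivity=0.30, false_positive_rate=0.01),
        "SHFD": SourcePlan(sensitivity=0.20, false_positive_rate=0.01),
    }


class SimulationConfig(BaseModel):
    """Full description of one synthetic study world."""

    n_patients: int = Field(default=186, ge=1)
    seed: int = 0
    diagnosis_year: int = 2013
    agents: dict[str, AgentPlan] = Field(default_factory=_default_agents)
    sources: dict[str, SourcePlan] = Field(default_factory=_default_sources)
    radiotherapy: RadiotherapyPlan = Field(default_factory=RadiotherapyPlan)
    covariates: CovariatePlan = Field(default_factory=CovariatePlan)
    abstraction_sensitivity: float = Field(default=1.0, ge=0.0, le=1.0)
    abstraction_dose_noise_sd: float = Field(default=0.0, ge=0.0)
    emit_planning_claims: bool = True

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if not self.agents:
            raise ValueError("at least one agent plan required")
        return self


def load_simulation_config(path: str | Path) -> SimulationConfig:
    return SimulationConfig(**(yaml.safe_load(Path(path).read_text()) or {}))


def default_scenario() -> SimulationConfig:
    with resources.as_file(
        resources.files("claims2tx").joinpath("data/demo_scenario.yaml")
    ) as p:
        return load_simulation_config(p)


# -- truth containers ------------------------------------------------------

@dataclass(frozen=True)
class TruthEpisode:
    patient_id: str
    agent: str
    modality: str
    dates: tuple[date, ...]


@dataclass(frozen=True)
class TruthRT:
    patient_id: str
    dates: tuple[date, ...]
    schedule: str
    planned_fractions: int
    complete: bool

    @property
    def n_fractions(self) -> int:
        return len(self.dates)

    @property
    def total_gy(self) -> float:
        return min(self.n_fractions * TRUE_GY_PER_FRACTION[self.schedule], MAX_TOTAL_GY)


@dataclass
class Cohort:
    config: SimulationConfig
    profiles: dict[str, PatientProfile]
    episodes: list[TruthEpisode]
    rt: dict[str, TruthRT]


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


def _next_weekday(d: date) -> date:
    while d.weekday() >= 5:
        d += timedelta(days=1)
    return d


def _weekday_sequence(start: date, n: int, gap_after: int = -1, gap_days: int = 0) -> list[date]:
    """n consecutive weekday dates, with an optional gap inserted after
    fraction index ``gap_after`` (0-based)."""
    out: list[date] = []
    d = _next_weekday(start)
    for i in range(n):
        out.append(d)
        d = d + timedelta(days=1)
        if i == gap_after and gap_days > 0:
            d += timedelta(days=gap_days)
        d = _next_weekday(d)
    return out


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw patient covariates, true systemic exposures and true RT courses."""
    rng = _rng(config.seed, 0)
    n = config.n_patients
    cov = config.covariates
    width = len(str(n))

    profiles: dict[str, PatientProfile] = {}
    diag_base = date(config.diagnosis_year, 1, 1)
    for i in range(n):
        pid = f"P{i + 1:0{width}d}"
        age = float(np.clip(rng.normal(cov.age_mean, cov.age_sd), *cov.age_range))
        height = float(np.clip(rng.normal(cov.height_mean_cm, cov.height_sd_cm), 140.0, 195.0))
        weight = float(np.clip(rng.normal(cov.weight_mean_kg, cov.weight_sd_kg), *cov.weight_range_kg))
        dx = diag_base + timedelta(days=int(rng.integers(0, 365)))
        profiles[pid] = PatientProfile(
            patient_id=pid,
            diagnosis_date=dx,
            age_at_diagnosis=age,
            height_cm=height,
            weight_kg=weight,
            serum_creatinine_mg_dl=cov.serum_creatinine_mg_dl,
        )

    episodes: list[TruthEpisode] = []
    for agent, plan in config.agents.items():
        counts = sorted(plan.cycles)
        probs = np.array([plan.cycles[c] for c in counts], dtype=float)
        probs = probs / probs.sum()
        for pid, prof in profiles.items():
            if rng.random() >= plan.prevalence:
                continue
            n_cycles = int(rng.choice(counts, p=probs))
            offset = int(rng.integers(plan.start_offset_days[0], plan.start_offset_days[1] + 1))
            start = prof.diagnosis_date + timedelta(days=offset)
            dates = tuple(start + timedelta(days=k * plan.cycle_days) for k in range(n_cycles))
            episodes.append(TruthEpisode(pid, agent, plan.modality, dates))

    rt: dict[str, TruthRT] = {}
    plan = config.radiotherapy
    schedules = sorted(plan.schedule_mix)
    sprobs = np.array([plan.schedule_mix[s] for s in schedules], dtype=float)
    sprobs = sprobs / sprobs.sum()
    for pid, prof in profiles.items():
        if rng.random() >= plan.prevalence:
            continue
        schedule = str(rng.choice(schedules, p=sprobs))
        lo, hi = _PLANNED_FRACTIONS[schedule]
        planned = int(rng.integers(lo, hi + 1))
        achieved = planned
        complete = True
        if rng.random() < plan.incompletion_probability:
            achieved = int(rng.integers(3, planned))
            complete = False
        gap_after, gap_days = -1, 0
        if achieved > 4 and rng.random() < plan.interruption_probability:
            gap_after = int(rng.integers(1, achieved - 1))
            gap_days = int(rng.integers(plan.interruption_gap_days[0], plan.interruption_gap_days[1] + 1))
        offset = int(rng.integers(plan.start_offset_days[0], plan.start_offset_days[1] + 1))
        start = prof.diagnosis_date + timedelta(days=offset)
        dates = tuple(_weekday_sequence(start, achieved, gap_after, gap_days))
        rt[pid] = TruthRT(pid, dates, schedule, planned, complete)

    return Cohort(config=config, profiles=profiles, episodes=episodes, rt=rt)


# -- claims emission -------------------------------------------------------

def _agent_code(agent: str, modality: str, code_map: CodeMap) -> str:
    return min(code_map.codes_for(agent))


def emit_claims(
    cohort: Cohort, code_map: Optional[CodeMap] = None
) -> list[ClaimRecord]:
    """Render the truth into noisy multi-source claim lines.

    Per (episode, source): the whole episode is captured with the source's
    sensitivity; captured episodes drop individual dates at ``date_dropout``
    but always keep at least one.  False-positive episodes are injected per
    (source, agent) among truly unexposed patients.
    """
    config = cohort.config
    code_map = code_map or default_code_map()
    rng = _rng(config.seed, 1)
    claims: list[ClaimRecord] = []

    def emit(pid: str, dates, code: str, source: str, claim_type: str) -> None:
        claims.extend(
            ClaimRecord(pid, d, code, source=source, claim_type=claim_type)
            for d in dates
        )

    def thin(dates: tuple[date, ...], dropout: float) -> list[date]:
        if dropout <= 0.0:
            return list(dates)
        keep = rng.random(len(dates)) >= dropout
        if not keep.any():
            keep[rng.integers(0, len(dates))] = True
        return [d for d, k in zip(dates, keep) if k]

    exposed: dict[str, set[str]] = {}
    for ep in cohort.episodes:
        exposed.setdefault(ep.agent, set()).add(ep.patient_id)

    for source, splan in config.sources.items():
        for ep in cohort.episodes:
            if rng.random() >= splan.sensitivity:
                continue
            code = _agent_code(ep.agent, ep.modality, code_map)
            ctype = PHARMACY if ep.modality == ENDOCRINE else MEDICAL
            emit(ep.patient_id, thin(ep.dates, splan.date_dropout), code, source, ctype)

        # false-positive systemic episodes: short billing-artifact runs
        if splan.false_positive_rate > 0:
            for agent, plan in config.agents.items():
                code = _agent_code(agent, plan.modality, code_map)
                ctype = PHARMACY if plan.modality == ENDOCRINE else MEDICAL
                hit = set(exposed.get(agent, ()))
                for pid, prof in cohort.profiles.items():
                    if pid in hit or rng.random() >= splan.false_positive_rate:
                        continue
                    length = int(rng.choice(splan.fp_episode_lengths))
                    start = prof.diagnosis_date + timedelta(days=int(rng.integers(30, 300)))
                    emit(
                        pid,
                        [start + timedelta(days=k * plan.cycle_days) for k in range(length)],
                        code, source, ctype,
                    )

        # radiotherapy fractions
        rt_codes = sorted(code_map.rt_delivery_codes & set(_RT_EMIT_CODES)) or sorted(
            code_map.rt_delivery_codes
        )
        for pid, truth in cohort.rt.items():
            if rng.random() >= splan.sensitivity:
                continue
            code = rt_codes[int(rng.integers(0, len(rt_codes)))]
            kept = thin(truth.dates, splan.date_dropout)
            if config.emit_planning_claims:
                emit(pid, [truth.dates[0] - timedelta(days=7)], _RT_PLANNING_CODE, source, MEDICAL)
            emit(pid, kept, code, source, MEDICAL)
        if splan.false_positive_rate > 0:
            for pid, prof in cohort.profiles.items():
                if pid in cohort.rt or rng.random() >= splan.false_positive_rate:
                    continue
                start = _next_weekday(
                    prof.diagnosis_date + timedelta(days=int(rng.integers(60, 300)))
                )
                emit(
                    pid,
                    _weekday_sequence(start, int(rng.integers(1, 4))),
                    rt_codes[0], source, MEDICAL,
                )

    claims.sort(key=lambda c: (c.patient_id, c.service_date, c.code, c.source))
    return claims


# -- abstraction emission --------------------------------------------------

ABSTRACTION_COLUMNS = [
    "patient_id", "record_type", "agent", "modality", "received",
    "n_cycles", "cumulative_dose", "rt_fractions", "rt_total_gy", "rt_complete",
]


def emit_abstraction(
    cohort: Cohort, regimens: Optional[RegimenTable] = None
) -> pd.DataFrame:
    """Gold-standard abstraction records derived from the truth.

    One row per patient x agent (record_type ``agent``) and one radiotherapy
    row per patient (record_type ``radiotherapy``).  With abstraction
    sensitivity < 1 some truly treated patients are recorded untreated,
    mimicking registry incompleteness; optional multiplicative noise perturbs
    abstracted chemo doses.
    """
    config = cohort.config
    regimens = regimens or default_regimen_table()
    rng = _rng(config.seed, 2)
    truth_by_patient: dict[tuple[str, str], TruthEpisode] = {
        (ep.patient_id, ep.agent): ep for ep in cohort.episodes
    }
    rows = []
    for pid, prof in cohort.profiles.items():
        for agent, plan in config.agents.items():
            ep = truth_by_patient.get((pid, agent))
            received = ep is not None and rng.random() < config.abstraction_sensitivity
            n_cycles = len(ep.dates) if received else 0
            dose = np.nan
            if received and plan.modality == CHEMO and agent in regimens:
                dose = cumulative_chemo_dose(agent, n_cycles, prof, regimens).cumulative_dose
                if config.abstraction_dose_noise_sd > 0:
                    dose *= max(0.0, 1.0 + rng.normal(0.0, config.abstraction_dose_noise_sd))
            rows.append(
                dict(
                    patient_id=pid, record_type="agent", agent=agent,
                    modality=plan.modality, received=int(received),
                    n_cycles=n_cycles if received else 0,
                    cumulative_dose=dose, rt_fractions=np.nan,
                    rt_total_gy=np.nan, rt_complete=np.nan,
                )
            )
        truth_rt = cohort.rt.get(pid)
        received = truth_rt is not None and rng.random() < config.abstraction_sensitivity
        rows.append(
            dict(
                patient_id=pid, record_type="radiotherapy", agent="",
                modality="radiotherapy", received=int(received),
                n_cycles=0, cumulative_dose=np.nan,
                rt_fractions=truth_rt.n_fractions if received else np.nan,
                rt_total_gy=truth_rt.total_gy if received else np.nan,
                rt_complete=float(truth_rt.complete) if received else np.nan,
            )
        )
    return pd.DataFrame(rows, columns=ABSTRACTION_COLUMNS)


# -- frame/export helpers --------------------------------------------------

def truth_exposure_frame(cohort: Cohort) -> pd.DataFrame:
    """Binary truth indicators (patients x agents + any_chemo)."""
    agents = list(cohort.config.agents)
    df = pd.DataFrame(
        0, index=pd.Index(cohort.profiles, name="patient_id"), columns=agents, dtype=int
    )
    for ep in cohort.episodes:
        df.loc[ep.patient_id, ep.agent] = 1
    chemo = [a for a, p in cohort.config.agents.items() if p.modality == CHEMO]
    df["any_chemo"] = df[chemo].max(axis=1) if chemo else 0
    df["radiotherapy"] = [int(pid in cohort.rt) for pid in df.index]
    return df


def claims_frame(claims: list[ClaimRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [c.patient_id for c in claims],
            "service_date": [c.service_date.isoformat() for c in claims],
            "code": [c.code for c in claims],
            "source": [c.source for c in claims],
            "claim_type": [c.claim_type for c in claims],
        }
    )


def profiles_frame(cohort: Cohort) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in cohort.profiles.values()],
            "diagnosis_date": [p.diagnosis_date.isoformat() for p in cohort.profiles.values()],
            "age_at_diagnosis": [round(p.age_at_diagnosis, 2) for p in cohort.profiles.values()],
            "height_cm": [round(p.height_cm, 2) for p in cohort.profiles.values()],
            "weight_kg": [round(p.weight_kg, 2) for p in cohort.profiles.values()],
            "serum_creatinine_mg_dl": [p.serum_creatinine_mg_dl for p in cohort.profiles.values()],
        }
    )


def write_simulation(out_dir: str | Path, cohort: Cohort, code_map: Optional[CodeMap] = None) -> dict[str, Path]:
    """Write claims.csv, abstraction.csv, profiles.csv, truth.csv to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "claims": out / "claims.csv",
        "abstraction": out / "abstraction.csv",
        "profiles": out / "profiles.csv",
        "truth": out / "truth.csv",
    }
    claims_frame(emit_claims(cohort, code_map)).to_csv(paths["claims"], index=False)
    emit_abstraction(cohort).to_csv(paths["abstraction"], index=False)
    profiles_frame(cohort).to_csv(paths["profiles"], index=False)
    truth_exposure_frame(cohort).to_csv(paths["truth"])
    return paths
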