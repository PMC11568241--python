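"""Cumulative chemotherapy dose estimation and radiotherapy course assembly.

Chemotherapy
    Cumulative dose = guideline per-cycle dose x number of claim-identified
    cycles.  mg/m2 agents are scaled by the patient's body surface area
    (Mosteller); carboplatin uses the Calvert equation at a target AUC of 6
    with a Cockcroft-Gault (female) GFR computed from age, weight, and an
    assumed serum creatinine.

Radiotherapy
    Distinct delivery dates inside a one-year window are split into courses
    wherever consecutive fractions are more than 30 days apart.  Total dose in
    Gy is assigned from the fraction count through a tiered schedule: counts
    matching a recognised fractionation schedule use that schedule's dose per
    fraction; <= 16 non-matching fractions get 2.67 Gy each; 17-21 get
    16 x 2.66 Gy plus 2.50 Gy for the remainder; >= 22 get 2.0 Gy each; no
    dose is estimated below 5 fractions, and estimates are capped at 66 Gy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, timedelta
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .identify import PatientProfile

MG_PER_M2 = "mg_per_m2"
AUC = "auc"

STANDARD = "standard"
HYPOFRACTIONATED = "hypofractionated"
APBI = "apbi"
NONSTANDARD = "nonstandard"

COMPLETE = "complete"
INCOMPLETE = "incomplete"

BSA_BASED = "bsa_based"
CALVERT = "calvert"

#: Gy per fraction for counts that match a recognised fractionation schedule.
#: Only the non-matching tiers are pinned down by the estimation rule; these
#: canonical values (34 Gy / 10 fractions for accelerated partial breast
#: irradiation, 2.66 Gy for 15-16-fraction hypofractionation) are config
#: entries a user may override.
DEFAULT_SCHEDULE_GY_PER_FRACTION: dict[int, float] = {10: 3.4, 15: 2.66, 16: 2.66}

MAX_TOTAL_GY = 66.0


class DoseError(ValueError):
    pass


# -- closed-form clinical formulas ----------------------------------------

def mosteller_bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area in m2: sqrt(height_cm x weight_kg / 3600)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise DoseError("height and weight must be positive")
    return math.sqrt(height_cm * weight_kg / 3600.0)


def cockcroft_gault_gfr_female(
    age_years: float, weight_kg: float, serum_creatinine_mg_dl: float
) -> float:
    """Creatinine clearance (mL/min) for women:
    0.85 x (140 - age) x weight / (72 x serum creatinine)."""
    if not 18 <= age_years < 140:
        raise DoseError(f"age {age_years} outside [18, 140)")
    if weight_kg <= 0 or serum_creatinine_mg_dl <= 0:
        raise DoseError("weight and serum creatinine must be positive")
    return 0.85 * (140.0 - age_years) * weight_kg / (72.0 * serum_creatinine_mg_dl)


def calvert_dose(auc_target: float, gfr_ml_min: float) -> float:
    """Carboplatin dose in mg: AUC x (GFR + 25)."""
    if auc_target <= 0:
        raise DoseError("AUC target must be positive")
    if gfr_ml_min < 0:
        raise DoseError("GFR must be non-negative")
    return auc_target * (gfr_ml_min + 25.0)


# -- regimen table ---------------------------------------------------------

@dataclass(frozen=True)
class RegimenEntry:
    unit: str  # MG_PER_M2 or AUC
    cycle_days: int = 21
    dose_per_cycle: Optional[float] = None  # mg/m2 for MG_PER_M2 entries
    auc: Optional[float] = None  # target AUC for AUC entries

    def __post_init__(self) -> None:
        if self.unit == MG_PER_M2:
            if self.dose_per_cycle is None or self.dose_per_cycle <= 0:
                raise DoseError("mg/m2 regimen needs a positive dose_per_cycle")
        elif self.unit == AUC:
            if self.auc is None or self.auc <= 0:
                raise DoseError("AUC regimen needs a positive auc target")
        else:
            raise DoseError(f"unknown regimen unit {self.unit!r}")
        if self.cycle_days <= 0:
            raise DoseError("cycle_days must be positive")


@dataclass
class RegimenTable:
    entries: dict[str, RegimenEntry]

    def require(self, agent: str) -> RegimenEntry:
        try:
            return self.entries[agent]
        except KeyError:
            raise DoseError(f"agent {agent!r} absent from regimen table") from None

    def __contains__(self, agent: str) -> bool:
        return agent in self.entries


def load_regimen_table(path: str | Path) -> RegimenTable:
    """Load a regimen table from YAML/JSON: agent -> {unit, dose_per_cycle|auc, cycle_days}."""
    payload = yaml.safe_load(Path(path).read_text())
    if not payload:
        raise DoseError(f"{path}: empty regimen table")
    entries = {}
    for agent, body in payload.items():
        entries[str(agent).lower()] = RegimenEntry(
            unit=body.get("unit", MG_PER_M2),
            cycle_days=int(body.get("cycle_days", 21)),
            dose_per_cycle=body.get("dose_per_cycle"),
            auc=body.get("auc"),
        )
    return RegimenTable(entries)


def default_regimen_table() -> RegimenTable:
    with resources.as_file(
        resources.files("claims2tx").joinpath("data/default_regimens.yaml")
    ) as p:
        return load_regimen_table(p)


@dataclass(frozen=True)
class DoseEstimate:
    patient_id: str
    agent: str
    n_cycles: int
    bsa_m2: Optional[float]
    cumulative_dose: float  # mg (Calvert) or BSA-scaled mg (mg/m2 agents)
    method: str  # BSA_BASED or CALVERT


def cumulative_chemo_dose(
    agent: str,
    n_cycles: int,
    profile: PatientProfile,
    regimens: Optional[RegimenTable] = None,
    use_bsa: bool = True,
) -> DoseEstimate:
    """Cumulative dose = per-cycle dose x cycle count.

    ``use_bsa=False`` reports mg/m2 agents un-scaled (per-cycle dose x cycles
    in mg/m2), the sensitivity-analysis convention; Calvert dosing is
    unaffected by the flag.
    """
    if n_cycles < 0:
        raise DoseError("n_cycles must be non-negative")
    regimens = regimens or default_regimen_table()
    entry = regimens.require(agent)
    if entry.unit == AUC:
        gfr = cockcroft_gault_gfr_female(
            profile.age_at_diagnosis, profile.weight_kg, profile.serum_creatinine_mg_dl
        )
        per_cycle = calvert_dose(entry.auc, gfr)
        return DoseEstimate(
            patient_id=profile.patient_id,
            agent=agent,
            n_cycles=n_cycles,
            bsa_m2=None,
            cumulative_dose=per_cycle * n_cycles,
            method=CALVERT,
        )
    bsa = mosteller_bsa(profile.height_cm, profile.weight_kg)
    per_cycle = entry.dose_per_cycle * (bsa if use_bsa else 1.0)
    return DoseEstimate(
        patient_id=profile.patient_id,
        agent=agent,
        n_cycles=n_cycles,
        bsa_m2=bsa,
        cumulative_dose=per_cycle * n_cycles,
        method=BSA_BASED,
    )


# -- radiotherapy ----------------------------------------------------------

@dataclass
class RadiotherapyCourse:
    patient_id: str
    fraction_dates: tuple[date, ...]
    schedule: str
    completion: str
    estimated_total_gy: Optional[float]
    is_boost: bool = False

    @property
    def n_fractions(self) -> int:
        return len(self.fraction_dates)

    @property
    def start(self) -> date:
        return self.fraction_dates[0]

    @property
    def end(self) -> date:
        return self.fraction_dates[-1]


def assign_rt_dose(
    n_fractions: int,
    schedule_gy_per_fraction: Optional[Mapping[int, float]] = None,
    cap_gy: float = MAX_TOTAL_GY,
) -> Optional[float]:
    """Estimated total Gy from a fraction count (see module docstring).

    Returns ``None`` below 5 fractions; the estimate never exceeds ``cap_gy``.
    """
    if n_fractions < 0:
        raise DoseError("fraction count must be non-negative")
    if n_fractions < 5:
        return None
    table = (
        DEFAULT_SCHEDULE_GY_PER_FRACTION
        if schedule_gy_per_fraction is None
        else dict(schedule_gy_per_fraction)
    )
    if n_fractions in table:
        total = n_fractions * table[n_fractions]
    elif n_fractions <= 16:
        total = n_fractions * 2.67
    elif n_fractions <= 21:
        total = 16 * 2.66 + (n_fractions - 16) * 2.50
    else:
        total = n_fractions * 2.0
    return min(total, cap_gy)


def classify_schedule(n_fractions: int) -> str:
    if 25 <= n_fractions <= 28:
        return STANDARD
    if n_fractions in (15, 16):
        return HYPOFRACTIONATED
    if n_fractions == 10:
        return APBI
    return NONSTANDARD


def classify_completion(
    fraction_dates: Sequence[date],
    min_complete_fractions: int = 15,
    apbi_fractions: int = 10,
    apbi_max_gap_days: int = 1,
) -> str:
    """Course completion: reaching the hypofractionated minimum (>= 15
    fractions) counts as complete, as does a dense >= 10-fraction course
    whose inter-fraction gaps never exceed one day (the accelerated
    partial-breast pattern).  The rule table is configurable."""
    n = len(fraction_dates)
    if n >= min_complete_fractions:
        return COMPLETE
    if n >= apbi_fractions:
        gaps = [
            (b - a).days for a, b in zip(fraction_dates, fraction_dates[1:])
        ]
        if all(g <= apbi_max_gap_days for g in gaps):
            return COMPLETE
    return INCOMPLETE


def build_rt_courses(
    fraction_dates: Iterable[date],
    diagnosis_date: date,
    max_gap_days: int = 30,
    window_days: int = 365,
    patient_id: str = "",
    schedule_gy_per_fraction: Optional[Mapping[int, float]] = None,
    boost_window_days: Optional[int] = None,
) -> list[RadiotherapyCourse]:
    """Split windowed delivery dates into courses at gaps > ``max_gap_days``.

    The first course is the primary analysis unit.  With ``boost_window_days``
    set (must exceed ``max_gap_days``), a later course starting within that
    many days of the initial course's end is flagged as a boost.
    """
    if boost_window_days is not None and boost_window_days <= max_gap_days:
        raise DoseError("boost_window_days must exceed max_gap_days")
    window_end = diagnosis_date + timedelta(days=window_days)
    dates = sorted({d for d in fraction_dates if diagnosis_date <= d <= window_end})
    if not dates:
        return []
    runs: list[list[date]] = [[dates[0]]]
    for d in dates[1:]:
        if (d - runs[-1][-1]).days <= max_gap_days:
            runs[-1].append(d)
        else:
            runs.append([d])
    courses = []
    for i, run in enumerate(runs):
        run_t = tuple(run)
        courses.append(
            RadiotherapyCourse(
                patient_id=patient_id,
                fraction_dates=run_t,
                schedule=classify_schedule(len(run_t)),
                completion=classify_completion(run_t),
                estimated_total_gy=assign_rt_dose(
                    len(run_t), schedule_gy_per_fraction
                ),
                is_boost=(
                    i > 0
                    and boost_window_days is not None
                    and (run_t[0] - runs[0][-1]).days <= boost_window_days
                ),
            )
        )
    return courses
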