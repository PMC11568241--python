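"""Convert raw claim lines into per-patient treatment episodes and indicators.

A patient is classified as exposed to an agent when at least one matching
claim falls inside the treatment window (by default one year from the cancer
diagnosis).  Each distinct service date of an agent counts as one cycle:
same-day duplicate claim lines collapse, and the ordered list of service
dates defines the episode.  Pharmacy claims are matched against endocrine
NDCs only, medical claims against infusion chemotherapy / biologic HCPCS
codes; radiotherapy delivery claims are collected separately as fraction
dates (planning codes never count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .codes import (
    BIOLOGIC,
    CHEMO,
    ENDOCRINE,
    RT_DELIVERY,
    CodeMap,
    lookup,
)

#: Data sources recognised by default; additional names are accepted as long
#: as they appear in the claims being processed.
DEFAULT_SOURCES = ("APCD", "UCR_claims", "EMR", "SHFD")

MEDICAL = "medical"
PHARMACY = "pharmacy"

#: Which claim type may establish exposure for each systemic modality.
_MODALITY_CLAIM_TYPE = {CHEMO: MEDICAL, BIOLOGIC: MEDICAL, ENDOCRINE: PHARMACY}


class IdentificationError(ValueError):
    pass


@dataclass(frozen=True)
class ClaimRecord:
    """One billed service line (medical or pharmacy)."""

    patient_id: str
    service_date: date
    code: str
    source: str = "APCD"
    claim_type: str = MEDICAL

    def __post_init__(self) -> None:
        if not self.code:
            raise IdentificationError("claim with empty code")
        if self.claim_type not in (MEDICAL, PHARMACY):
            raise IdentificationError(f"unknown claim_type {self.claim_type!r}")


@dataclass
class PatientProfile:
    """Covariates needed for dose reconstruction and windowing."""

    patient_id: str
    diagnosis_date: date
    age_at_diagnosis: float
    height_cm: float
    weight_kg: float
    serum_creatinine_mg_dl: float = 0.8  # assumed fixed value; configurable

    def __post_init__(self) -> None:
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise IdentificationError(
                f"{self.patient_id}: non-positive height/weight"
            )
        if self.age_at_diagnosis < 18:
            raise IdentificationError(f"{self.patient_id}: age below 18")


@dataclass(frozen=True)
class TreatmentEpisode:
    """Per-patient, per-agent derived exposure; one cycle per service date."""

    patient_id: str
    agent: str
    modality: str
    service_dates: tuple[date, ...]
    source_set: frozenset[str]

    @property
    def n_cycles(self) -> int:
        return len(self.service_dates)

    def __post_init__(self) -> None:
        if any(
            b <= a for a, b in zip(self.service_dates, self.service_dates[1:])
        ):
            raise IdentificationError("service dates must be strictly increasing")


@dataclass
class ExposureMatrix:
    """Binary patient x agent indicators, one frame per source subset.

    Each frame is indexed by patient_id with one column per agent plus a
    derived ``any_chemo`` column (OR over chemotherapy-modality agents; the
    biologic trastuzumab does not count toward it).
    """

    frames: dict[str, pd.DataFrame]
    agent_modality: dict[str, str]

    def indicator(self, subset: str) -> pd.DataFrame:
        return self.frames[subset]


def _profiles_mapping(
    profiles: Mapping[str, PatientProfile] | Iterable[PatientProfile]
) -> dict[str, PatientProfile]:
    if isinstance(profiles, Mapping):
        return dict(profiles)
    return {p.patient_id: p for p in profiles}


def identify_exposures(
    claims: Sequence[ClaimRecord],
    code_map: CodeMap,
    profiles: Mapping[str, PatientProfile] | Iterable[PatientProfile],
    window_days: int = 365,
    exclude_patients: Iterable[str] = (),
    ndc_match: str = "prefix9",
) -> list[TreatmentEpisode]:
    """Derive systemic-therapy episodes from claim lines.

    Claims outside ``[diagnosis_date, diagnosis_date + window_days]`` are
    ignored, as are claims whose code does not match the map or whose claim
    type is inconsistent with the matched modality.  ``exclude_patients``
    supports manual removal of e.g. post-primary treatment courses.
    """
    if window_days <= 0:
        raise IdentificationError("window_days must be positive")
    prof = _profiles_mapping(profiles)
    excluded = set(exclude_patients)
    unknown = sorted({c.patient_id for c in claims} - set(prof) - excluded)
    if unknown:
        raise IdentificationError(
            f"claims reference unknown patient ids: {unknown[:10]}"
        )

    acc: dict[tuple[str, str], dict] = {}
    for claim in claims:
        if claim.patient_id in excluded:
            continue
        hit = lookup(claim.code, code_map, ndc_match=ndc_match)
        if hit is None:
            continue
        modality, agent = hit
        if agent is None or _MODALITY_CLAIM_TYPE.get(modality) != claim.claim_type:
            continue  # radiotherapy handled separately; wrong claim type ignored
        p = prof[claim.patient_id]
        if not (
            p.diagnosis_date
            <= claim.service_date
            <= p.diagnosis_date + timedelta(days=window_days)
        ):
            continue
        slot = acc.setdefault(
            (claim.patient_id, agent),
            {"modality": modality, "dates": set(), "sources": set()},
        )
        slot["dates"].add(claim.service_date)
        slot["sources"].add(claim.source)

    return [
        TreatmentEpisode(
            patient_id=pid,
            agent=agent,
            modality=slot["modality"],
            service_dates=tuple(sorted(slot["dates"])),
            source_set=frozenset(slot["sources"]),
        )
        for (pid, agent), slot in sorted(acc.items())
    ]


def identify_rt_fraction_dates(
    claims: Sequence[ClaimRecord],
    code_map: CodeMap,
    profiles: Mapping[str, PatientProfile] | Iterable[PatientProfile],
    window_days: int = 365,
    sources: Optional[Iterable[str]] = None,
) -> dict[str, list[date]]:
    """Distinct radiotherapy delivery dates per patient inside the window.

    Planning codes are never counted.  ``sources`` restricts which claim
    sources contribute (default: all).
    """
    prof = _profiles_mapping(profiles)
    allowed = set(sources) if sources is not None else None
    out: dict[str, set[date]] = {}
    for claim in claims:
        if allowed is not None and claim.source not in allowed:
            continue
        hit = lookup(claim.code, code_map)
        if hit is None or hit[0] != RT_DELIVERY or claim.claim_type != MEDICAL:
            continue
        p = prof.get(claim.patient_id)
        if p is None:
            raise IdentificationError(
                f"claims reference unknown patient ids: [{claim.patient_id!r}]"
            )
        if not (
            p.diagnosis_date
            <= claim.service_date
            <= p.diagnosis_date + timedelta(days=window_days)
        ):
            continue
        out.setdefault(claim.patient_id, set()).add(claim.service_date)
    return {pid: sorted(dates) for pid, dates in sorted(out.items())}


def build_exposure_matrix(
    episodes: Sequence[TreatmentEpisode],
    patient_ids: Sequence[str],
    subsets: Optional[Mapping[str, Iterable[str]]] = None,
    agents: Optional[Sequence[str]] = None,
    agent_modality: Optional[Mapping[str, str]] = None,
) -> ExposureMatrix:
    """Binary exposure indicators per requested source subset.

    An indicator is 1 iff at least one of the episode's contributing sources
    belongs to the subset; the subset union is therefore a logical OR and
    enlarging a subset can never lower an indicator.
    """
    known = set(DEFAULT_SOURCES) | {s for e in episodes for s in e.source_set}
    if subsets is None:
        subsets = {"all_sources": sorted(known)}
    for name, srcs in subsets.items():
        bad = set(srcs) - known
        if bad:
            raise IdentificationError(
                f"subset {name!r} names unknown sources: {sorted(bad)}"
            )

    modality = dict(agent_modality or {})
    for e in episodes:
        modality.setdefault(e.agent, e.modality)
    if agents is None:
        agents = sorted(modality)
    chemo_agents = [a for a in agents if modality.get(a) == CHEMO]

    frames: dict[str, pd.DataFrame] = {}
    for name, srcs in subsets.items():
        srcs = set(srcs)
        df = pd.DataFrame(0, index=pd.Index(patient_ids, name="patient_id"),
                          columns=list(agents), dtype=int)
        for e in episodes:
            if e.agent in df.columns and e.source_set & srcs:
                df.loc[e.patient_id, e.agent] = 1
        df["any_chemo"] = (
            df[chemo_agents].max(axis=1) if chemo_agents else 0
        )
        frames[name] = df
    return ExposureMatrix(frames=frames, agent_modality=modality)


# -- CSV plumbing ----------------------------------------------------------

def claims_from_frame(df: pd.DataFrame) -> list[ClaimRecord]:
    """Build claim records from a DataFrame; extra columns are tolerated."""
    required = {"patient_id", "service_date", "code"}
    missing = required - set(df.columns)
    if missing:
        raise IdentificationError(f"claims table missing columns: {sorted(missing)}")
    dates = pd.to_datetime(df["service_date"]).dt.date
    sources = df["source"] if "source" in df else pd.Series("APCD", index=df.index)
    ctypes = df["claim_type"] if "claim_type" in df else pd.Series(MEDICAL, index=df.index)
    return [
        ClaimRecord(
            patient_id=str(pid),
            service_date=d,
            code=str(code),
            source=str(src),
            claim_type=str(ct),
        )
        for pid, d, code, src, ct in zip(
            df["patient_id"], dates, df["code"], sources, ctypes
        )
    ]


def read_claims_csv(path: str | Path) -> list[ClaimRecord]:
    return claims_from_frame(pd.read_csv(path, dtype={"code": str, "patient_id": str}))


def profiles_from_frame(df: pd.DataFrame) -> dict[str, PatientProfile]:
    dx = pd.to_datetime(df["diagnosis_date"]).dt.date
    out = {}
    for i, row in enumerate(df.itertuples(index=False)):
        p = PatientProfile(
            patient_id=str(row.patient_id),
            diagnosis_date=dx.iloc[i],
            age_at_diagnosis=float(row.age_at_diagnosis),
            height_cm=float(row.height_cm),
            weight_kg=float(row.weight_kg),
            serum_creatinine_mg_dl=float(
                getattr(row, "serum_creatinine_mg_dl", 0.8)
            ),
        )
        out[p.patient_id] = p
    return out


def read_profiles_csv(path: str | Path) -> dict[str, PatientProfile]:
    return profiles_from_frame(pd.read_csv(path, dtype={"patient_id": str}))
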