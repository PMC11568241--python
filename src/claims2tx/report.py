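"""End-to-end pipeline orchestration and confidentiality-aware table rendering.

`run_pipeline` ties the stages together: claims -> exposure identification ->
dose / radiotherapy reconstruction -> agreement statistics against the
abstraction, and renders validation-style tables:

* per-agent 2x2 quadrants with kappa and diagnostic metrics (one row per
  agent plus an any-chemotherapy aggregate);
* a per-source / source-union panel;
* a chemotherapy dose ICC table;
* a radiotherapy completion table with a dose ICC row;
* quadrant percentage summaries.

Cell suppression masks counts below a confidentiality threshold (default
< 11) together with their derived percentages; complement suppression
additionally masks the smallest unsuppressed count in a row, since a row
total plus three cells would otherwise reveal the suppressed fourth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .agreement import (
    agreement_summary,
    contingency,
    icc_oneway,
    multi_source_panel,
)
from .codes import CHEMO, CodeMap, default_code_map
from .dose import (
    COMPLETE,
    RegimenTable,
    build_rt_courses,
    cumulative_chemo_dose,
    default_regimen_table,
)
from .identify import (
    ClaimRecord,
    PatientProfile,
    build_exposure_matrix,
    claims_from_frame,
    identify_exposures,
    identify_rt_fraction_dates,
    profiles_from_frame,
)

logger = logging.getLogger(__name__)

SUPPRESSED = "<suppressed>"

_QUADRANT_COLS = ["neither", "gold_only", "claims_only", "both"]


@dataclass
class ReportSpec:
    """What to emit and how to mask small cells."""

    tables: tuple[str, ...] = (
        "agents", "sources", "chemo_dose", "radiotherapy", "quadrants"
    )
    suppression_threshold: int = 11
    complement_suppression: bool = True
    output_format: str = "csv"  # csv | json | markdown
    ci_method: str = "wald"
    primary_sources: tuple[str, ...] = ("APCD", "UCR_claims")
    window_days: int = 365

    def __post_init__(self) -> None:
        if self.suppression_threshold < 0:
            raise ValueError("suppression threshold must be >= 0")
        if self.output_format not in ("csv", "json", "markdown"):
            raise ValueError(f"unknown output format {self.output_format!r}")


def suppress_cell(count: int, threshold: int) -> Union[int, str]:
    """Display value for a count cell: the count, or a suppression marker."""
    if count < 0:
        raise ValueError("count must be non-negative")
    return SUPPRESSED if count < threshold else count


def suppress_quadrants(
    df: pd.DataFrame,
    threshold: int,
    complement: bool = True,
    count_cols: Sequence[str] = tuple(_QUADRANT_COLS),
    pct_suffix: str = "_pct",
) -> pd.DataFrame:
    """Mask sub-threshold quadrant counts (and their percentages) in a table.

    With ``complement`` set, a row in which exactly one count was masked also
    has its smallest remaining count masked, so the row total cannot restore
    the primary suppression.
    """
    out = df.copy()
    cols = [c for c in count_cols if c in out.columns]
    out[cols] = out[cols].astype(object)
    for idx, row in df.iterrows():
        masked = [c for c in cols if row[c] < threshold]
        if complement and len(masked) == 1:
            rest = sorted(
                (c for c in cols if c not in masked), key=lambda c: row[c]
            )
            if rest:
                masked.append(rest[0])
        for c in masked:
            out.loc[idx, c] = SUPPRESSED
            pct = f"{c}{pct_suffix}"
            if pct in out.columns:
                out[pct] = out[pct].astype(object)
                out.loc[idx, pct] = SUPPRESSED
    return out


@dataclass
class ReportBundle:
    """Computed tables plus the spec used to render them."""

    tables: dict[str, pd.DataFrame]
    spec: ReportSpec
    log: list[str] = field(default_factory=list)

    def rendered(self) -> dict[str, pd.DataFrame]:
        """Tables with suppression applied where quadrant counts appear."""
        out = {}
        for name, df in self.tables.items():
            if {"both", "neither"}.issubset(df.columns):
                out[name] = suppress_quadrants(
                    df,
                    self.spec.suppression_threshold,
                    self.spec.complement_suppression,
                )
            else:
                out[name] = df
        return out

    def write(self, out_dir: str | Path) -> list[Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for name, df in self.rendered().items():
            if self.spec.output_format == "json":
                path = out / f"{name}.json"
                df.reset_index().to_json(path, orient="records", indent=1)
            elif self.spec.output_format == "markdown":
                path = out / f"{name}.md"
                path.write_text(df.to_markdown())
            else:
                path = out / f"{name}.csv"
                df.to_csv(path)
            written.append(path)
        return written


def _round1(x: Optional[float]) -> Optional[float]:
    return None if x is None else round(x, 1)


def _agent_row(name: str, gold: np.ndarray, claims: np.ndarray, ci_method: str) -> dict:
    t = contingency(gold, claims)
    res = agreement_summary(t, ci_method=ci_method)
    pct = t.quadrant_percentages()
    row = {
        "agent": name,
        "n": t.n,
        "neither": t.neither,
        "gold_only": t.gold_only,
        "claims_only": t.claims_only,
        "both": t.both,
        "neither_pct": round(pct["neither"], 1),
        "gold_only_pct": round(pct["gold_only"], 1),
        "claims_only_pct": round(pct["claims_only"], 1),
        "both_pct": round(pct["both"], 1),
        "kappa_pct": _round1(100 * res.kappa),
    }
    for m in ("sensitivity", "specificity", "ppv", "npv"):
        v = getattr(res, m)
        ci = getattr(res, f"{m}_ci")
        row[f"{m}_pct"] = _round1(None if v is None else 100 * v)
        row[f"{m}_lo_pct"] = _round1(None if ci is None else 100 * ci[0])
        row[f"{m}_hi_pct"] = _round1(None if ci is None else 100 * ci[1])
    return row


def run_pipeline(
    claims: Union[str, Path, pd.DataFrame, Sequence[ClaimRecord]],
    abstraction: Union[str, Path, pd.DataFrame],
    profiles: Union[str, Path, pd.DataFrame, dict[str, PatientProfile]],
    code_map: Optional[CodeMap] = None,
    regimens: Optional[RegimenTable] = None,
    spec: Optional[ReportSpec] = None,
    exclude_patients: Sequence[str] = (),
) -> ReportBundle:
    """Run identification, reconstruction and validation end to end.

    ``claims``/``abstraction``/``profiles`` accept CSV paths, DataFrames, or
    already-parsed objects.  The gold standard is the abstraction table (one
    agent row per patient x agent, one radiotherapy row per patient).
    """
    spec = spec or ReportSpec()
    code_map = code_map or default_code_map()
    regimens = regimens or default_regimen_table()
    log: list[str] = []

    def note(msg: str) -> None:
        log.append(msg)
        logger.info(msg)

    # -- inputs -----------------------------------------------------------
    if isinstance(claims, (str, Path)):
        claims = pd.read_csv(claims, dtype={"code": str, "patient_id": str})
    if isinstance(claims, pd.DataFrame):
        claim_records = claims_from_frame(claims)
    else:
        claim_records = list(claims)
    if isinstance(profiles, (str, Path)):
        profiles = pd.read_csv(profiles, dtype={"patient_id": str})
    if isinstance(profiles, pd.DataFrame):
        profiles = profiles_from_frame(profiles)
    if isinstance(abstraction, (str, Path)):
        abstraction = pd.read_csv(abstraction, dtype={"patient_id": str})
    note(f"inputs: {len(claim_records)} claims, {len(profiles)} profiles, "
         f"{len(abstraction)} abstraction rows")

    patient_ids = list(profiles)
    ab_agents = abstraction[abstraction["record_type"] == "agent"].copy()
    ab_rt = abstraction[abstraction["record_type"] == "radiotherapy"].copy()
    agents = sorted(ab_agents["agent"].unique())
    modality_of = dict(zip(ab_agents["agent"], ab_agents["modality"]))

    # -- identification ---------------------------------------------------
    episodes = identify_exposures(
        claim_records, code_map, profiles,
        window_days=spec.window_days, exclude_patients=exclude_patients,
    )
    sources_present = sorted({s for e in episodes for s in e.source_set})
    primary = [s for s in spec.primary_sources if s in sources_present] or sources_present
    subsets = {s: [s] for s in sources_present}
    subsets["primary"] = primary
    subsets["all_sources"] = sources_present
    matrix = build_exposure_matrix(
        episodes, patient_ids, subsets=subsets, agents=agents,
        agent_modality=modality_of,
    )
    note(f"identified {len(episodes)} episodes across sources {sources_present}")

    # -- gold standard ----------------------------------------------------
    gold = (
        ab_agents.pivot_table(
            index="patient_id", columns="agent", values="received", aggfunc="max"
        )
        .reindex(patient_ids)
        .fillna(0)
        .astype(int)
    )
    chemo_agents = [a for a in agents if modality_of.get(a) == CHEMO]
    gold["any_chemo"] = gold[chemo_agents].max(axis=1) if chemo_agents else 0

    tables: dict[str, pd.DataFrame] = {}
    claims_primary = matrix.indicator("primary")

    # -- per-agent agreement (validation-table analogue) ------------------
    if "agents" in spec.tables:
        rows = [
            _agent_row("any_chemo", gold["any_chemo"].values,
                       claims_primary["any_chemo"].values, spec.ci_method)
        ]
        rows += [
            _agent_row(a, gold[a].values, claims_primary[a].values, spec.ci_method)
            for a in agents
        ]
        tables["agents"] = pd.DataFrame(rows).set_index("agent")

    # -- per-source panel --------------------------------------------------
    if "sources" in spec.tables:
        panels = []
        for a in ["any_chemo"] + agents:
            per_source = pd.DataFrame(
                {s: matrix.indicator(s)[a] for s in sources_present},
                index=claims_primary.index,
            )
            panel = multi_source_panel(
                gold[a], per_source, subsets, ci_method=spec.ci_method
            )
            panel.insert(0, "agent", a)
            panels.append(panel.reset_index())
        tables["sources"] = pd.concat(panels, ignore_index=True).set_index(
            ["agent", "subset"]
        )

    # -- chemotherapy dose ICC --------------------------------------------
    ep_cycles = {(e.patient_id, e.agent): e.n_cycles for e in episodes}
    if "chemo_dose" in spec.tables:
        rows = []
        for a in chemo_agents:
            if a not in regimens:
                continue
            sub = ab_agents[(ab_agents["agent"] == a) & (ab_agents["received"] == 1)]
            pairs = []
            n_missing = 0
            for pid, gold_dose in zip(sub["patient_id"], sub["cumulative_dose"]):
                n_cycles = ep_cycles.get((pid, a), 0)
                if n_cycles == 0 or pd.isna(gold_dose):
                    n_missing += 1
                    continue
                est = cumulative_chemo_dose(a, n_cycles, profiles[pid], regimens)
                pairs.append((float(gold_dose), est.cumulative_dose))
            if len(pairs) < 3:
                note(f"dose ICC for {a}: only {len(pairs)} complete pairs, skipped")
                continue
            note(f"dose ICC for {a}: {len(pairs)} pairs, {n_missing} dropped")
            res = icc_oneway(pairs)
            rows.append(
                {
                    "agent": a, "n_pairs": res.n_pairs, "n_dropped": n_missing,
                    "icc_pct": round(100 * res.icc, 1),
                    "icc_lo_pct": round(100 * res.ci[0], 1),
                    "icc_hi_pct": round(100 * res.ci[1], 1),
                }
            )
        tables["chemo_dose"] = pd.DataFrame(
            rows, columns=["agent", "n_pairs", "n_dropped", "icc_pct",
                           "icc_lo_pct", "icc_hi_pct"]
        ).set_index("agent")

    # -- radiotherapy ------------------------------------------------------
    if "radiotherapy" in spec.tables:
        fraction_dates = identify_rt_fraction_dates(
            claim_records, code_map, profiles,
            window_days=spec.window_days, sources=primary,
        )
        claims_complete, claims_received, claims_gy = {}, {}, {}
        for pid in patient_ids:
            courses = build_rt_courses(
                fraction_dates.get(pid, []), profiles[pid].diagnosis_date,
                window_days=spec.window_days, patient_id=pid,
            )
            claims_received[pid] = bool(courses)
            initial = courses[0] if courses else None
            claims_complete[pid] = bool(initial and initial.completion == COMPLETE)
            claims_gy[pid] = initial.estimated_total_gy if initial else None

        rt_gold = ab_rt.set_index("patient_id").reindex(patient_ids)
        gold_received = rt_gold["received"].fillna(0).astype(bool)
        gold_complete = gold_received & (rt_gold["rt_complete"].fillna(0) > 0)
        cc = np.array([claims_complete[p] for p in patient_ids])
        cr = np.array([claims_received[p] for p in patient_ids])

        rows = [
            _agent_row("complete", gold_complete.values.astype(int), cc.astype(int),
                       spec.ci_method),
            _agent_row(
                "incomplete",
                (gold_received & ~gold_complete).values.astype(int),
                (cr & ~cc).astype(int),
                spec.ci_method,
            ),
        ]
        rt_table = pd.DataFrame(rows).set_index("agent")
        rt_table.index.name = "completion"
        tables["radiotherapy"] = rt_table

        pairs, n_missing = [], 0
        for pid in patient_ids:
            g = rt_gold.loc[pid, "rt_total_gy"]
            c = claims_gy[pid]
            if pd.isna(g) and c is None:
                continue
            if pd.isna(g) or c is None:
                n_missing += 1
                continue
            pairs.append((float(g), float(c)))
        if len(pairs) >= 3:
            note(f"RT dose ICC: {len(pairs)} pairs, {n_missing} one-sided dropped")
            res = icc_oneway(pairs)
            tables["radiotherapy_dose"] = pd.DataFrame(
                [{
                    "n_pairs": res.n_pairs, "n_dropped": n_missing,
                    "icc_pct": round(100 * res.icc, 1),
                    "icc_lo_pct": round(100 * res.ci[0], 1),
                    "icc_hi_pct": round(100 * res.ci[1], 1),
                }],
                index=pd.Index(["radiotherapy_gy"], name="measure"),
            )

    # -- quadrant percentage summary --------------------------------------
    if "quadrants" in spec.tables and "agents" in tables:
        tables["quadrants"] = tables["agents"][
            ["n", "neither", "gold_only", "claims_only", "both",
             "neither_pct", "gold_only_pct", "claims_only_pct", "both_pct"]
        ].copy()

    return ReportBundle(tables=tables, spec=spec, log=log)
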