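"""Agent-to-billing-code dictionaries driving claims-based treatment detection.

Chemotherapy and biologic (trastuzumab) agents are detected through HCPCS/CPT
procedure codes on medical claims; endocrine agents through NDC product codes
on pharmacy claims; radiotherapy through a fixed list of external-beam /
brachytherapy *delivery* codes, with treatment-*planning* codes tracked only so
they can be excluded from fraction counts.

The bundled default map covers five infusion chemotherapy agents, tamoxifen,
three aromatase inhibitors, trastuzumab, and the nine delivery codes used for
radiotherapy fraction counting.  The HCPCS J-codes and NDC entries are
best-effort, user-overridable defaults (code dictionaries such as CanMED
evolve); the radiotherapy delivery list is fixed by the method.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

# Modality labels used throughout the package.
CHEMO = "chemo"
ENDOCRINE = "endocrine"
BIOLOGIC = "biologic"
RT_DELIVERY = "radiotherapy_delivery"
RT_PLANNING = "radiotherapy_planning"
MODALITIES = (CHEMO, ENDOCRINE, BIOLOGIC, RT_DELIVERY, RT_PLANNING)

SYSTEMIC_MODALITIES = (CHEMO, ENDOCRINE, BIOLOGIC)

_MODALITY_ALIASES = {
    "chemo": CHEMO,
    "chemotherapy": CHEMO,
    "endocrine": ENDOCRINE,
    "hormone": ENDOCRINE,
    "biologic": BIOLOGIC,
    "radiotherapy_delivery": RT_DELIVERY,
    "rt_delivery": RT_DELIVERY,
    "radiotherapy": RT_DELIVERY,
    "radiotherapy_planning": RT_PLANNING,
    "rt_planning": RT_PLANNING,
}

_NORM_RE = re.compile(r"[^A-Z0-9]")


class CodeMapError(ValueError):
    """Raised when a code map fails validation (collisions, empty sets, ...)."""


def normalize_code(code: str) -> str:
    """Canonical form of a billing code: uppercase, alphanumerics only.

    Thousands separators sometimes typeset inside HCPCS codes ("77,401") and
    NDC hyphens ("00093-0782") are stripped, so exact matching is insensitive
    to formatting.
    """
    return _NORM_RE.sub("", str(code).strip().upper())


@dataclass
class CodeMap:
    """Validated lookup tables from billing code to (modality, agent)."""

    chemo_codes: dict[str, frozenset[str]]
    endocrine_ndc: dict[str, frozenset[str]]
    biologic_codes: dict[str, frozenset[str]]
    rt_delivery_codes: frozenset[str]
    rt_planning_codes: frozenset[str]
    _index: dict[str, tuple[str, Optional[str]]] = field(
        default=None, repr=False, compare=False
    )
    _ndc9_index: dict[str, str] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.chemo_codes = {a: frozenset(map(normalize_code, s)) for a, s in self.chemo_codes.items()}
        self.endocrine_ndc = {a: frozenset(map(normalize_code, s)) for a, s in self.endocrine_ndc.items()}
        self.biologic_codes = {a: frozenset(map(normalize_code, s)) for a, s in self.biologic_codes.items()}
        self.rt_delivery_codes = frozenset(map(normalize_code, self.rt_delivery_codes))
        self.rt_planning_codes = frozenset(map(normalize_code, self.rt_planning_codes))
        self._validate()
        self._build_index()

    # -- validation -------------------------------------------------------
    def _agent_sets(self) -> Iterable[tuple[str, Optional[str], frozenset[str]]]:
        for agent, codes in self.chemo_codes.items():
            yield CHEMO, agent, codes
        for agent, codes in self.endocrine_ndc.items():
            yield ENDOCRINE, agent, codes
        for agent, codes in self.biologic_codes.items():
            yield BIOLOGIC, agent, codes
        yield RT_DELIVERY, None, self.rt_delivery_codes
        yield RT_PLANNING, None, self.rt_planning_codes

    def _validate(self) -> None:
        seen: dict[str, tuple[str, Optional[str]]] = {}
        for modality, agent, codes in self._agent_sets():
            # a named agent must carry codes; RT sets may be absent entirely
            if agent is not None and not codes:
                raise CodeMapError(f"empty code set for {modality}/{agent}")
            for code in codes:
                if code in seen and seen[code] != (modality, agent):
                    m2, a2 = seen[code]
                    raise CodeMapError(
                        f"code {code!r} mapped to both {m2}/{a2 or 'n/a'} "
                        f"and {modality}/{agent or 'n/a'}"
                    )
                seen[code] = (modality, agent)
        if self.rt_delivery_codes & self.rt_planning_codes:
            raise CodeMapError(
                "radiotherapy delivery and planning code sets overlap: "
                f"{sorted(self.rt_delivery_codes & self.rt_planning_codes)}"
            )

    def _build_index(self) -> None:
        idx: dict[str, tuple[str, Optional[str]]] = {}
        for modality, agent, codes in self._agent_sets():
            for code in codes:
                idx[code] = (modality, agent)
        # 9-digit (labeler+product) prefix index for NDC matching.
        ndc9: dict[str, str] = {}
        drop: set[str] = set()
        for agent, codes in self.endocrine_ndc.items():
            for code in codes:
                if code.isdigit() and len(code) >= 9:
                    pfx = code[:9]
                    if pfx in ndc9 and ndc9[pfx] != agent:
                        logger.warning(
                            "NDC prefix %s ambiguous between %s and %s; "
                            "prefix matching disabled for it", pfx, ndc9[pfx], agent,
                        )
                        drop.add(pfx)
                    ndc9[pfx] = agent
        for pfx in drop:
            del ndc9[pfx]
        self._index = idx
        self._ndc9_index = ndc9

    # -- queries ----------------------------------------------------------
    @property
    def agents(self) -> dict[str, str]:
        """Mapping agent name -> modality, over systemic agents."""
        out = {a: CHEMO for a in self.chemo_codes}
        out.update({a: ENDOCRINE for a in self.endocrine_ndc})
        out.update({a: BIOLOGIC for a in self.biologic_codes})
        return out

    def codes_for(self, agent: str) -> frozenset[str]:
        for table in (self.chemo_codes, self.endocrine_ndc, self.biologic_codes):
            if agent in table:
                return table[agent]
        raise KeyError(agent)


def lookup(
    code: str, code_map: CodeMap, ndc_match: str = "prefix9"
) -> Optional[tuple[str, Optional[str]]]:
    """Resolve a billing code to ``(modality, agent)``, or ``None`` for no match.

    Matching is exact on the normalized code.  With ``ndc_match="prefix9"``
    (default) an 11-digit NDC additionally matches a stored NDC sharing its
    9-digit labeler+product prefix; ``ndc_match="exact"`` disables this.
    A failed lookup is a value, not an error.
    """
    norm = normalize_code(code)
    if not norm:
        return None
    hit = code_map._index.get(norm)
    if hit is not None:
        return hit
    if ndc_match == "prefix9" and norm.isdigit() and len(norm) > 9:
        agent = code_map._ndc9_index.get(norm[:9])
        if agent is not None:
            return (ENDOCRINE, agent)
    return None


# -- I/O -------------------------------------------------------------------

def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    return "json" if path.suffix.lower() == ".json" else "csv"


def _rows_from_file(path: Path, fmt: str) -> list[tuple[str, str, str]]:
    rows: list[tuple[str, str, str]] = []
    if fmt == "json":
        payload = json.loads(path.read_text())
        if isinstance(payload, list):  # records [{modality, agent, code}, ...]
            for rec in payload:
                rows.append((rec["modality"], rec.get("agent") or "", rec["code"]))
        else:  # nested {modality: {agent: [codes]}} or {modality: [codes]} for RT
            for modality, body in payload.items():
                if isinstance(body, dict):
                    for agent, codes in body.items():
                        rows.extend((modality, agent, c) for c in codes)
                else:
                    rows.extend((modality, "", c) for c in body)
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {
                "modality", "agent", "code"
            }.issubset(reader.fieldnames):
                raise CodeMapError(
                    f"{path}: expected header with modality,agent,code columns"
                )
            for rec in reader:
                rows.append((rec["modality"], rec.get("agent") or "", rec["code"]))
    return rows


def load_code_map(path: str | Path, format: Optional[str] = None) -> CodeMap:
    """Load and validate a code map from CSV (``modality,agent,code``) or JSON.

    Duplicate (modality, agent, code) rows collapse with a logged warning;
    the same code under two agents raises :class:`CodeMapError` naming both.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    rows = _rows_from_file(path, fmt)
    if not rows:
        raise CodeMapError(f"{path}: no code entries found")

    tables: dict[str, dict[str, set[str]]] = {m: {} for m in MODALITIES}
    seen: set[tuple[str, str, str]] = set()
    for raw_modality, agent, code in rows:
        modality = _MODALITY_ALIASES.get(str(raw_modality).strip().lower())
        if modality is None:
            raise CodeMapError(f"unknown modality {raw_modality!r}")
        agent = str(agent).strip().lower()
        if modality in (RT_DELIVERY, RT_PLANNING):
            agent = ""
        elif not agent:
            raise CodeMapError(f"missing agent for {modality} code {code!r}")
        norm = normalize_code(code)
        key = (modality, agent, norm)
        if key in seen:
            logger.warning("duplicate code map entry collapsed: %s", key)
            continue
        seen.add(key)
        tables[modality].setdefault(agent, set()).add(norm)

    return CodeMap(
        chemo_codes=tables[CHEMO],
        endocrine_ndc=tables[ENDOCRINE],
        biologic_codes=tables[BIOLOGIC],
        rt_delivery_codes=frozenset().union(*tables[RT_DELIVERY].values()) if tables[RT_DELIVERY] else frozenset(),
        rt_planning_codes=frozenset().union(*tables[RT_PLANNING].values()) if tables[RT_PLANNING] else frozenset(),
    )


def write_code_map(code_map: CodeMap, path: str | Path, format: Optional[str] = None) -> None:
    """Write a code map back to CSV or JSON; round-trips through load_code_map."""
    path = Path(path)
    fmt = _infer_format(path, format)
    rows = sorted(
        (m, a or "", c)
        for m, a, codes in code_map._agent_sets()
        for c in codes
    )
    if fmt == "json":
        payload = [{"modality": m, "agent": a or None, "code": c} for m, a, c in rows]
        path.write_text(json.dumps(payload, indent=1))
    else:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["modality", "agent", "code"])
            writer.writerows(rows)


def default_code_map() -> CodeMap:
    """The bundled default map (editable stand-in; see module docstring)."""
    with resources.as_file(
        resources.files("claims2tx").joinpath("data/default_code_map.csv")
    ) as p:
        return load_code_map(p)
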