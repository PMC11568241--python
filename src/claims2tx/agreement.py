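"""Agreement statistics between claims-derived and gold-standard treatment data.

Binary treatment indicators are compared through a 2x2 contingency table
(gold standard = manual abstraction on the rows, claims on the columns):
Cohen's kappa with its asymptotic (Fleiss-Cohen-Everitt) standard error, and
sensitivity / specificity / PPV / NPV with Wald 95% confidence intervals
(Wilson available).  Continuous dose agreement uses the one-way
random-effects intraclass correlation ICC = s2_B / (s2_B + s2_W) with an
F-distribution confidence interval, optionally after a natural-log
transform.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


class AgreementError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 gold-vs-claims counts: rows gold (+/-), columns claims (+/-)."""

    both: int
    gold_only: int
    claims_only: int
    neither: int

    def __post_init__(self) -> None:
        for name in ("both", "gold_only", "claims_only", "neither"):
            if getattr(self, name) < 0:
                raise AgreementError(f"negative count in {name}")

    @property
    def n(self) -> int:
        return self.both + self.gold_only + self.claims_only + self.neither

    @property
    def gold_positive(self) -> int:
        return self.both + self.gold_only

    @property
    def gold_negative(self) -> int:
        return self.neither + self.claims_only

    @property
    def claims_positive(self) -> int:
        return self.both + self.claims_only

    @property
    def claims_negative(self) -> int:
        return self.neither + self.gold_only

    def transpose(self) -> "ContingencyTable":
        """Swap the two raters (gold <-> claims)."""
        return ContingencyTable(
            both=self.both,
            gold_only=self.claims_only,
            claims_only=self.gold_only,
            neither=self.neither,
        )

    def quadrant_percentages(self) -> dict[str, float]:
        """Quadrant shares in percent: gold_only / claims_only / both / neither."""
        if self.n == 0:
            raise AgreementError("empty table")
        return {
            q: 100.0 * getattr(self, q) / self.n
            for q in ("gold_only", "claims_only", "both", "neither")
        }


def contingency(
    gold: Sequence[int], claims: Sequence[int]
) -> ContingencyTable:
    """Exact quadrant counts from two aligned binary vectors."""
    g = np.asarray(gold)
    c = np.asarray(claims)
    if g.shape != c.shape:
        raise AgreementError(f"length mismatch: {g.shape} vs {c.shape}")
    g = g.astype(bool)
    c = c.astype(bool)
    return ContingencyTable(
        both=int((g & c).sum()),
        gold_only=int((g & ~c).sum()),
        claims_only=int((~g & c).sum()),
        neither=int((~g & ~c).sum()),
    )


@dataclass
class AgreementResult:
    """Container for the agreement statistics of one 2x2 comparison.

    Metrics with a zero denominator are reported as ``None`` (missing), not
    as an error; confidence intervals are clipped to [0, 1].
    """

    table: ContingencyTable
    kappa: Optional[float] = None
    kappa_ci: Optional[tuple[float, float]] = None
    observed_agreement: Optional[float] = None
    expected_agreement: Optional[float] = None
    sensitivity: Optional[float] = None
    sensitivity_ci: Optional[tuple[float, float]] = None
    specificity: Optional[float] = None
    specificity_ci: Optional[tuple[float, float]] = None
    ppv: Optional[float] = None
    ppv_ci: Optional[tuple[float, float]] = None
    npv: Optional[float] = None
    npv_ci: Optional[tuple[float, float]] = None


def _kappa_se(p: np.ndarray, kappa: float, pe: float, n: int) -> float:
    # Fleiss, Cohen & Everitt (1969) large-sample variance of kappa, 2x2 case;
    # p is the matrix of cell proportions with gold on rows.
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    a = sum(
        p[i, i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2 for i in range(2)
    )
    b = (1.0 - kappa) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(2)
        for j in range(2)
        if i != j
    )
    c = (kappa - pe * (1.0 - kappa)) ** 2
    var = (a + b - c) / (n * (1.0 - pe) ** 2)
    return math.sqrt(max(var, 0.0))


def cohens_kappa(t: ContingencyTable, alpha: float = 0.05) -> AgreementResult:
    """Chance-corrected agreement kappa = (Po - Pe) / (1 - Pe).

    Po is the observed concordance, Pe the concordance expected from the row
    and column margins.  When Pe = 1 (a degenerate margin) kappa is defined
    as 0 with a warning.
    """
    n = t.n
    if n == 0:
        raise AgreementError("empty table")
    po = (t.both + t.neither) / n
    pe = (t.gold_positive * t.claims_positive + t.gold_negative * t.claims_negative) / n**2
    if pe >= 1.0:
        warnings.warn("expected agreement is 1; kappa defined as 0")
        return AgreementResult(
            table=t, kappa=0.0, kappa_ci=(0.0, 0.0),
            observed_agreement=po, expected_agreement=pe,
        )
    kappa = (po - pe) / (1.0 - pe)
    p = (
        np.array(
            [[t.both, t.gold_only], [t.claims_only, t.neither]], dtype=float
        )
        / n
    )
    se = _kappa_se(p, kappa, pe, n)
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    ci = (kappa - z * se, min(kappa + z * se, 1.0))
    return AgreementResult(
        table=t, kappa=kappa, kappa_ci=ci,
        observed_agreement=po, expected_agreement=pe,
    )


def _proportion_ci(
    count: int, nobs: int, alpha: float, method: str
) -> tuple[float, float]:
    sm_method = {"wald": "normal", "wilson": "wilson"}[method]
    lo, hi = proportion_confint(count, nobs, alpha=alpha, method=sm_method)
    return (max(float(lo), 0.0), min(float(hi), 1.0))


def diagnostic_metrics(
    t: ContingencyTable, ci_method: str = "wald", alpha: float = 0.05
) -> AgreementResult:
    """Sensitivity, specificity, PPV, NPV against the gold standard.

    Each metric gets a 95% CI (Wald by default, Wilson via ``ci_method``);
    a metric whose denominator is zero is reported as missing.
    """
    if t.n == 0:
        raise AgreementError("empty table")
    if ci_method not in ("wald", "wilson"):
        raise AgreementError(f"unknown ci_method {ci_method!r}")
    result = AgreementResult(table=t)
    for attr, count, denom in (
        ("sensitivity", t.both, t.gold_positive),
        ("specificity", t.neither, t.gold_negative),
        ("ppv", t.both, t.claims_positive),
        ("npv", t.neither, t.claims_negative),
    ):
        if denom == 0:
            continue
        setattr(result, attr, count / denom)
        setattr(result, f"{attr}_ci", _proportion_ci(count, denom, alpha, ci_method))
    return result


def agreement_summary(
    t: ContingencyTable, ci_method: str = "wald", alpha: float = 0.05
) -> AgreementResult:
    """Kappa plus diagnostic metrics in one result."""
    res = diagnostic_metrics(t, ci_method=ci_method, alpha=alpha)
    k = cohens_kappa(t, alpha=alpha)
    res.kappa, res.kappa_ci = k.kappa, k.kappa_ci
    res.observed_agreement = k.observed_agreement
    res.expected_agreement = k.expected_agreement
    return res


# -- intraclass correlation ------------------------------------------------

@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci: tuple[float, float]
    sigma2_between: float
    sigma2_within: float
    n_pairs: int
    log_transformed: bool
    n_dropped: int = 0


def icc_oneway(
    pairs: Iterable[tuple[float, float]],
    log_transform: bool = False,
    alpha: float = 0.05,
) -> ICCResult:
    """One-way random-effects ICC for paired gold/claims measurements.

    Each subject contributes k = 2 ratings.  The between-subject variance is
    estimated as max(0, (MSB - MSW)/2) and the within variance as MSW, so the
    ICC is truncated at 0.  The CI uses the exact F-distribution bounds for
    the one-way model, clipped to [0, 1] for consistency with the truncated
    point estimate.  Pairs with a missing side are dropped (pairwise
    deletion) and counted in ``n_dropped``.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or (arr.size and arr.shape[1] != 2):
        raise AgreementError("pairs must be (gold, claims) tuples")
    complete = arr[~np.isnan(arr).any(axis=1)] if arr.size else arr
    n_dropped = len(arr) - len(complete)
    n = len(complete)
    if n < 3:
        raise AgreementError(f"need >= 3 complete pairs, got {n}")
    if log_transform:
        bad = np.where((complete <= 0).any(axis=1))[0]
        if bad.size:
            i = int(bad[0])
            raise AgreementError(
                f"non-positive value under log transform in pair {i}: "
                f"{tuple(complete[i])}"
            )
        complete = np.log(complete)

    k = 2
    subject_means = complete.mean(axis=1)
    grand = complete.mean()
    msb = k * float(((subject_means - grand) ** 2).sum()) / (n - 1)
    msw = float(((complete - subject_means[:, None]) ** 2).sum()) / (n * (k - 1))
    sigma2_between = max(0.0, (msb - msw) / k)
    sigma2_within = msw
    total = sigma2_between + sigma2_within
    if total == 0.0:
        warnings.warn("zero total variance; ICC defined as 0")
        return ICCResult(0.0, (0.0, 1.0), 0.0, 0.0, n, log_transform, n_dropped)
    icc = sigma2_between / total

    dfb, dfw = n - 1, n * (k - 1)
    if msw == 0.0:
        ci = (1.0, 1.0)
    else:
        f_obs = msb / msw
        fl = f_obs / stats.f.ppf(1.0 - alpha / 2.0, dfb, dfw)
        fu = f_obs * stats.f.ppf(1.0 - alpha / 2.0, dfw, dfb)
        ci = (
            min(max((fl - 1.0) / (fl + k - 1.0), 0.0), 1.0),
            min(max((fu - 1.0) / (fu + k - 1.0), 0.0), 1.0),
        )
    return ICCResult(icc, ci, sigma2_between, sigma2_within, n, log_transform, n_dropped)


# -- multi-source panels ---------------------------------------------------

def multi_source_panel(
    gold: pd.Series,
    source_indicators: pd.DataFrame,
    subsets: Mapping[str, Sequence[str]],
    ci_method: str = "wald",
) -> pd.DataFrame:
    """Agreement statistics of source unions against one gold column.

    ``source_indicators`` holds one binary column per source, aligned on the
    same patients as ``gold``; for each named subset the component columns
    are OR-ed and compared to the gold standard.  Returns one row per subset
    in the given order.
    """
    if not gold.index.equals(source_indicators.index):
        raise AgreementError("gold and source indicators are misaligned")
    rows = []
    for name, cols in subsets.items():
        missing = set(cols) - set(source_indicators.columns)
        if missing:
            raise AgreementError(f"subset {name!r}: unknown sources {sorted(missing)}")
        union = source_indicators[list(cols)].max(axis=1)
        res = agreement_summary(contingency(gold.values, union.values), ci_method)
        rows.append(
            {
                "subset": name,
                "n": res.table.n,
                "kappa": res.kappa,
                "kappa_lo": res.kappa_ci[0],
                "kappa_hi": res.kappa_ci[1],
                **{
                    m: getattr(res, m)
                    for m in ("sensitivity", "specificity", "ppv", "npv")
                },
            }
        )
    return pd.DataFrame(rows).set_index("subset")
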