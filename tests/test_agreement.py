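"""Agreement statistics: kappa, diagnostic metrics, one-way ICC, panels."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from claims2tx import (
    ContingencyTable,
    agreement_summary,
    cohens_kappa,
    contingency,
    diagnostic_metrics,
    icc_oneway,
    multi_source_panel,
)
from claims2tx.agreement import AgreementError

counts = st.integers(min_value=0, max_value=500)


# -- contingency -----------------------------------------------------------

def test_contingency_enumeration():
    t = contingency([1, 1, 0, 0], [1, 0, 1, 0])
    assert (t.both, t.gold_only, t.claims_only, t.neither) == (1, 1, 1, 1)


def test_contingency_identical_vectors():
    t = contingency([1, 0, 1], [1, 0, 1])
    assert t.gold_only == t.claims_only == 0


def test_contingency_length_mismatch():
    with pytest.raises(AgreementError):
        contingency([1, 0], [1])


def test_quadrant_percentages_published_fixture(cyclophosphamide_table):
    """The published quadrant shares: 8.6 / 6.4 / 33.3 / 51.6 percent."""
    pct = cyclophosphamide_table.quadrant_percentages()
    assert pct["gold_only"] == pytest.approx(8.6, abs=0.05)
    assert pct["claims_only"] == pytest.approx(6.45, abs=0.05)
    assert pct["both"] == pytest.approx(33.33, abs=0.05)
    assert pct["neither"] == pytest.approx(51.61, abs=0.05)


# -- kappa -----------------------------------------------------------------

def test_kappa_published_fixture(cyclophosphamide_table):
    res = cohens_kappa(cyclophosphamide_table)
    assert res.observed_agreement == pytest.approx(158 / 186)
    assert res.kappa == pytest.approx(0.6886, abs=5e-4)


def test_kappa_hand_values():
    assert cohens_kappa(ContingencyTable(50, 0, 0, 50)).kappa == pytest.approx(1.0)
    res = cohens_kappa(ContingencyTable(both=40, gold_only=10, claims_only=10, neither=40))
    assert res.observed_agreement == pytest.approx(0.8)
    assert res.expected_agreement == pytest.approx(0.5)
    assert res.kappa == pytest.approx(0.6)


def test_kappa_degenerate_margins_warns():
    with pytest.warns(UserWarning):
        res = cohens_kappa(ContingencyTable(both=10, gold_only=0, claims_only=0, neither=0))
    assert res.kappa == 0.0


def test_kappa_empty_table_rejected():
    with pytest.raises(AgreementError):
        cohens_kappa(ContingencyTable(0, 0, 0, 0))


def test_kappa_matches_statsmodels(cyclophosphamide_table):
    """Independent cross-check against statsmodels' kappa on the same table."""
    from statsmodels.stats.inter_rater import cohens_kappa as sm_kappa

    t = cyclophosphamide_table
    table = np.array([[t.both, t.gold_only], [t.claims_only, t.neither]], float)
    sm = sm_kappa(table, return_results=True)
    ours = cohens_kappa(t)
    assert ours.kappa == pytest.approx(float(sm.kappa), abs=1e-12)
    assert ours.kappa_ci[0] == pytest.approx(float(sm.kappa_low), abs=1e-6)


@settings(derandomize=True, max_examples=200)
@given(both=counts, gold_only=counts, claims_only=counts, neither=counts)
def test_kappa_transpose_symmetry(both, gold_only, claims_only, neither):
    """Kappa is invariant to swapping the two raters."""
    if both + gold_only + claims_only + neither == 0:
        return
    t = ContingencyTable(both, gold_only, claims_only, neither)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert cohens_kappa(t).kappa == pytest.approx(
                cohens_kappa(t.transpose()).kappa, abs=1e-12
            )


def test_kappa_randomized_symmetry_and_independence_suite():
    """1000 random tables: transpose symmetry everywhere, and exactly zero
    kappa on tables constructed with independent margins."""
    rng = np.random.default_rng(20260925)
    for _ in range(1000):
        a, b, c, d = rng.integers(0, 200, size=4)
        if a + b + c + d == 0:
            continue
        t = ContingencyTable(int(a), int(b), int(c), int(d))
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            k1 = cohens_kappa(t).kappa
            k2 = cohens_kappa(t.transpose()).kappa
        assert k1 == pytest.approx(k2, abs=1e-12)
    for _ in range(200):
        N = int(rng.integers(2, 40))
        r = int(rng.integers(1, N))
        s = int(rng.integers(1, N))
        # outer-product table: margins exactly independent
        t = ContingencyTable(
            both=r * s, gold_only=r * (N - s), claims_only=(N - r) * s,
            neither=(N - r) * (N - s),
        )
        assert cohens_kappa(t).kappa == pytest.approx(0.0, abs=1e-12)


def test_kappa_one_iff_diagonal():
    assert cohens_kappa(ContingencyTable(7, 0, 0, 13)).kappa == pytest.approx(1.0)
    assert cohens_kappa(ContingencyTable(7, 1, 0, 13)).kappa < 1.0


# -- diagnostic metrics ----------------------------------------------------

def test_metrics_published_cyclophosphamide(cyclophosphamide_table):
    res = diagnostic_metrics(cyclophosphamide_table)
    assert 100 * res.sensitivity == pytest.approx(79.5, abs=0.05)
    assert 100 * res.specificity == pytest.approx(88.9, abs=0.05)
    assert 100 * res.ppv == pytest.approx(83.8, abs=0.05)
    assert 100 * res.npv == pytest.approx(85.7, abs=0.05)
    lo, hi = res.sensitivity_ci
    assert 100 * lo == pytest.approx(70.5, abs=0.05)
    assert 100 * hi == pytest.approx(88.4, abs=0.05)


def test_metrics_published_radiotherapy_complete():
    t = ContingencyTable(both=57, gold_only=30, claims_only=14, neither=61)
    res = diagnostic_metrics(t)
    assert 100 * res.sensitivity == pytest.approx(65.5, abs=0.05)
    assert 100 * res.specificity == pytest.approx(81.3, abs=0.05)
    assert 100 * res.ppv == pytest.approx(80.3, abs=0.05)
    assert 100 * res.npv == pytest.approx(67.0, abs=0.05)


def test_metrics_perfect_table():
    res = diagnostic_metrics(ContingencyTable(both=30, gold_only=0, claims_only=0, neither=20))
    assert res.sensitivity == res.specificity == res.ppv == res.npv == 1.0


def test_metrics_zero_denominator_missing():
    res = diagnostic_metrics(ContingencyTable(both=0, gold_only=0, claims_only=3, neither=7))
    assert res.sensitivity is None  # no gold positives
    assert res.specificity is not None


def test_metrics_all_zero_rejected():
    with pytest.raises(AgreementError):
        diagnostic_metrics(ContingencyTable(0, 0, 0, 0))


def test_wald_ci_width_shrinks_with_n():
    widths = []
    for n in (10, 100, 10000):
        k = int(0.8 * n)
        res = diagnostic_metrics(ContingencyTable(both=k, gold_only=n - k, claims_only=0, neither=1))
        lo, hi = res.sensitivity_ci
        widths.append(hi - lo)
    assert widths[0] > widths[1] > widths[2]
    assert widths[2] < 0.02


def test_wilson_ci_differs_from_wald(cyclophosphamide_table):
    wald = diagnostic_metrics(cyclophosphamide_table, ci_method="wald")
    wilson = diagnostic_metrics(cyclophosphamide_table, ci_method="wilson")
    assert wald.sensitivity == wilson.sensitivity
    assert wald.sensitivity_ci != wilson.sensitivity_ci


# -- ICC -------------------------------------------------------------------

def icc_oracle(pairs):
    """Brute-force one-way ANOVA decomposition, written independently."""
    n = len(pairs)
    values = [v for p in pairs for v in p]
    grand = sum(values) / (2 * n)
    means = [(g + c) / 2 for g, c in pairs]
    msb = 2 * sum((m - grand) ** 2 for m in means) / (n - 1)
    msw = sum((g - m) ** 2 + (c - m) ** 2 for (g, c), m in zip(pairs, means)) / n
    s2b = max(0.0, (msb - msw) / 2)
    total = s2b + msw
    return s2b / total if total > 0 else 0.0


def test_icc_identical_pairs_is_one():
    pairs = [(x, x) for x in (1.0, 2.0, 5.0, 9.0)]
    res = icc_oneway(pairs)
    assert res.icc == 1.0
    assert res.sigma2_within == 0.0


def test_icc_independent_noise_near_zero():
    rng = np.random.default_rng(7)
    pairs = list(zip(rng.normal(size=200), rng.normal(size=200)))
    assert icc_oneway(pairs).icc == pytest.approx(0.0, abs=0.1)


def test_icc_six_pair_hand_oracle():
    pairs = [(480.0, 470.0), (320.0, 330.0), (600.0, 610.0),
             (150.0, 140.0), (275.0, 300.0), (510.0, 505.0)]
    res = icc_oneway(pairs)
    assert res.icc == pytest.approx(icc_oracle(pairs), abs=1e-10)
    assert res.ci[0] < res.icc < res.ci[1]


def test_icc_randomized_oracle_suite():
    """200 random <= 10-pair inputs agree with the brute-force ANOVA oracle
    to 1e-10."""
    rng = np.random.default_rng(20260925)
    for _ in range(200):
        n = int(rng.integers(3, 11))
        subject = rng.normal(0, rng.uniform(0.1, 5), size=n)
        noise = rng.normal(0, rng.uniform(0.01, 3), size=(n, 2))
        pairs = [(s + e1, s + e2) for s, (e1, e2) in zip(subject, noise)]
        assert icc_oneway(pairs).icc == pytest.approx(icc_oracle(pairs), abs=1e-10)


def test_icc_matches_pingouin():
    """Independent cross-check of point estimate and CI against pingouin's
    one-way (ICC1) implementation."""
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(11)
    subject = rng.normal(0, 2, size=30)
    pairs = [(s + rng.normal(0, 0.7), s + rng.normal(0, 0.7)) for s in subject]
    df = pd.DataFrame(
        {
            "targets": list(range(30)) * 2,
            "raters": ["gold"] * 30 + ["claims"] * 30,
            "score": [p[0] for p in pairs] + [p[1] for p in pairs],
        }
    )
    icc1 = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="score").iloc[0]
    res = icc_oneway(pairs)
    assert res.icc == pytest.approx(float(icc1["ICC"]), abs=1e-9)
    lo, hi = icc1["CI95"]  # pingouin rounds its interval to 2 dp
    assert res.ci[0] == pytest.approx(lo, abs=5e-3)
    assert res.ci[1] == pytest.approx(hi, abs=5e-3)


def test_icc_log_transform():
    pairs = [(100.0, 110.0), (200.0, 190.0), (400.0, 420.0), (800.0, 790.0)]
    res = icc_oneway(pairs, log_transform=True)
    assert res.log_transformed
    assert res.icc == pytest.approx(icc_oracle([(np.log(g), np.log(c)) for g, c in pairs]), abs=1e-10)
    with pytest.raises(AgreementError, match="pair"):
        icc_oneway([(1.0, 2.0), (0.0, 3.0), (4.0, 5.0)], log_transform=True)


def test_icc_missing_pairs_dropped():
    pairs = [(1.0, 1.1), (2.0, np.nan), (3.0, 3.2), (4.0, 4.1)]
    res = icc_oneway(pairs)
    assert res.n_pairs == 3
    assert res.n_dropped == 1
    with pytest.raises(AgreementError):
        icc_oneway([(1.0, 1.0), (2.0, 2.0)])


# -- multi-source panel ----------------------------------------------------

def test_panel_single_source_equals_direct():
    idx = pd.Index([f"P{i}" for i in range(8)], name="patient_id")
    gold = pd.Series([1, 1, 1, 1, 0, 0, 0, 0], index=idx)
    src = pd.DataFrame(
        {"A": [1, 1, 0, 0, 0, 0, 1, 0], "B": [0, 0, 1, 1, 0, 0, 0, 0]}, index=idx
    )
    panel = multi_source_panel(gold, src, {"A": ["A"], "B": ["B"], "AB": ["A", "B"]})
    direct = agreement_summary(contingency(gold.values, src["A"].values))
    assert panel.loc["A", "kappa"] == pytest.approx(direct.kappa)
    assert panel.loc["A", "sensitivity"] == pytest.approx(direct.sensitivity)


def test_panel_disjoint_half_coverage_unions_to_full_sensitivity():
    """Two disjoint sources each catching half the gold positives: union
    sensitivity is 100%."""
    idx = pd.Index([f"P{i}" for i in range(8)], name="patient_id")
    gold = pd.Series([1, 1, 1, 1, 0, 0, 0, 0], index=idx)
    src = pd.DataFrame(
        {"A": [1, 1, 0, 0, 0, 0, 0, 0], "B": [0, 0, 1, 1, 0, 0, 0, 0]}, index=idx
    )
    panel = multi_source_panel(gold, src, {"A": ["A"], "B": ["B"], "AB": ["A", "B"]})
    assert panel.loc["A", "sensitivity"] == 0.5
    assert panel.loc["B", "sensitivity"] == 0.5
    assert panel.loc["AB", "sensitivity"] == 1.0
    assert (panel["sensitivity"]["AB"] >= panel["sensitivity"]).all()


def test_panel_misaligned_rejected():
    gold = pd.Series([1, 0], index=["P1", "P2"])
    src = pd.DataFrame({"A": [1, 0]}, index=["P1", "P3"])
    with pytest.raises(AgreementError, match="misaligned"):
        multi_source_panel(gold, src, {"A": ["A"]})
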