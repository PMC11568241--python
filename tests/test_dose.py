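"""Dose arithmetic closed forms and radiotherapy course construction."""

from datetime import date, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from claims2tx import (
    assign_rt_dose,
    build_rt_courses,
    calvert_dose,
    classify_completion,
    cockcroft_gault_gfr_female,
    cumulative_chemo_dose,
    mosteller_bsa,
)
from claims2tx.dose import COMPLETE, DoseError, INCOMPLETE

DX = date(2013, 3, 1)


def weekdays(start: date, n: int) -> list[date]:
    out, d = [], start
    while len(out) < n:
        if d.weekday() < 5:
            out.append(d)
        d += timedelta(days=1)
    return out


# -- closed forms ----------------------------------------------------------

@pytest.mark.parametrize(
    "height,weight,expected",
    [(180, 80, 2.0), (160, 56.25, 1.5811), (150, 24, 1.0)],
)
def test_mosteller_bsa(height, weight, expected):
    assert mosteller_bsa(height, weight) == pytest.approx(expected, abs=1e-4)


def test_mosteller_rejects_nonpositive():
    with pytest.raises(DoseError):
        mosteller_bsa(0, 70)


def test_cockcroft_gault_female():
    assert cockcroft_gault_gfr_female(50, 70, 0.8) == pytest.approx(92.9688, abs=1e-3)
    assert cockcroft_gault_gfr_female(139, 72, 0.85) == pytest.approx(1.0)
    with pytest.raises(DoseError):
        cockcroft_gault_gfr_female(50, 70, 0.0)
    with pytest.raises(DoseError):
        cockcroft_gault_gfr_female(140, 70, 0.8)


def test_calvert_dose():
    assert calvert_dose(6, 92.9688) == pytest.approx(707.8125, abs=1e-3)
    assert calvert_dose(6, 0) == 150.0
    assert calvert_dose(1, 75) == 100.0
    with pytest.raises(DoseError):
        calvert_dose(6, -1)


@given(gfr=st.floats(min_value=0, max_value=200))
@settings(derandomize=True, max_examples=50)
def test_calvert_affine_in_gfr(gfr):
    assert calvert_dose(6, gfr) - calvert_dose(6, 0) == pytest.approx(6 * gfr)


def test_cumulative_dose_bsa_agent(profile, regimens):
    """Doxorubicin at the guideline 60 mg/m2, BSA 2.0, 4 cycles -> 480 mg."""
    est = cumulative_chemo_dose("doxorubicin", 4, profile, regimens)
    assert est.bsa_m2 == pytest.approx(2.0)
    assert est.cumulative_dose == pytest.approx(480.0)
    assert est.method == "bsa_based"


def test_cumulative_dose_zero_cycles(profile, regimens):
    assert cumulative_chemo_dose("paclitaxel", 0, profile, regimens).cumulative_dose == 0.0


def test_cumulative_dose_carboplatin(profile, regimens):
    """Calvert at AUC 6 with GFR from (age 50, 70 kg, 0.8 mg/dL): 6 cycles."""
    profile.weight_kg = 70.0
    est = cumulative_chemo_dose("carboplatin", 6, profile, regimens)
    assert est.method == "calvert"
    assert est.cumulative_dose == pytest.approx(6 * 707.8125, rel=1e-6)


def test_cumulative_dose_unknown_agent(profile, regimens):
    with pytest.raises(DoseError, match="absent"):
        cumulative_chemo_dose("nivolumab", 2, profile, regimens)


def test_cumulative_dose_linear_in_cycles_and_bsa(profile, regimens):
    one = cumulative_chemo_dose("docetaxel", 1, profile, regimens).cumulative_dose
    five = cumulative_chemo_dose("docetaxel", 5, profile, regimens).cumulative_dose
    assert five == pytest.approx(5 * one)
    # scaling BSA by k scales the dose by k: quadruple weight*height product
    profile.height_cm *= 2
    profile.weight_kg *= 2
    doubled = cumulative_chemo_dose("docetaxel", 1, profile, regimens).cumulative_dose
    assert doubled == pytest.approx(2 * one)


def test_use_bsa_flag_reports_per_m2(profile, regimens):
    est = cumulative_chemo_dose("docetaxel", 4, profile, regimens, use_bsa=False)
    assert est.cumulative_dose == pytest.approx(75 * 4)


# -- radiotherapy dose tiers ----------------------------------------------

def expected_rt_dose(n: int):
    """Independent restatement of the tiered rule for the full unit table."""
    if n < 5:
        return None
    if n == 10:
        total = 34.0
    elif n in (15, 16):
        total = n * 2.66
    elif n <= 16:
        total = n * 2.67
    elif n <= 21:
        total = 16 * 2.66 + (n - 16) * 2.50
    else:
        total = n * 2.0
    return min(total, 66.0)


@pytest.mark.parametrize("n", range(0, 46))
def test_assign_rt_dose_full_table(n):
    got = assign_rt_dose(n)
    want = expected_rt_dose(n)
    if want is None:
        assert got is None
    else:
        assert got == pytest.approx(want, abs=1e-9)
        assert got <= 66.0


def test_assign_rt_dose_key_values():
    assert assign_rt_dose(12) == pytest.approx(32.04)
    assert assign_rt_dose(20) == pytest.approx(52.56)
    assert assign_rt_dose(4) is None
    assert assign_rt_dose(40) == 66.0
    with pytest.raises(DoseError):
        assign_rt_dose(-1)


def test_assign_rt_dose_monotone_within_tiers():
    """Each tier is non-decreasing and obeys the 66 Gy cap; the tier
    boundaries themselves step down by construction of the rule."""
    for tier in (range(5, 10), range(11, 15), range(15, 17), range(17, 22),
                 range(22, 60)):
        doses = [assign_rt_dose(n) for n in tier]
        assert all(b >= a for a, b in zip(doses, doses[1:]))
        assert all(d <= 66.0 for d in doses)


# -- course construction ---------------------------------------------------

def test_single_course_from_weekday_run():
    dates = weekdays(date(2013, 6, 3), 25)
    (course,) = build_rt_courses(dates, DX)
    assert course.n_fractions == 25
    assert course.schedule == "standard"
    assert course.completion == COMPLETE
    assert course.estimated_total_gy == pytest.approx(50.0)


def test_gap_splits_courses():
    first = weekdays(date(2013, 6, 3), 15)
    second = weekdays(first[-1] + timedelta(days=40), 10)
    courses = build_rt_courses(first + second, DX)
    assert [c.n_fractions for c in courses] == [15, 10]


def test_window_excludes_late_fractions():
    assert build_rt_courses([DX + timedelta(days=370)], DX) == []
    assert build_rt_courses([], DX) == []


def test_course_partition_property():
    """Windowed dates are partitioned across courses: nothing lost, nothing
    duplicated, order preserved."""
    a = weekdays(date(2013, 5, 6), 8)
    b = weekdays(date(2013, 8, 1), 12)
    c = [DX + timedelta(days=400)]  # dropped by the window
    courses = build_rt_courses(a + b + c, DX)
    flat = [d for course in courses for d in course.fraction_dates]
    assert flat == sorted(set(a + b))


def test_boost_flag():
    first = weekdays(date(2013, 5, 6), 16)
    boost = weekdays(first[-1] + timedelta(days=35), 5)
    plain = build_rt_courses(first + boost, DX)
    assert [c.is_boost for c in plain] == [False, False]
    flagged = build_rt_courses(first + boost, DX, boost_window_days=60)
    assert [c.is_boost for c in flagged] == [False, True]
    with pytest.raises(DoseError):
        build_rt_courses(first, DX, boost_window_days=10)


@pytest.mark.parametrize(
    "n,consecutive,expected",
    [(25, False, COMPLETE), (16, False, COMPLETE), (7, True, INCOMPLETE),
     (10, True, COMPLETE), (10, False, INCOMPLETE)],
)
def test_classify_completion(n, consecutive, expected):
    if consecutive:
        dates = [date(2013, 6, 3) + timedelta(days=i) for i in range(n)]
    else:
        dates = weekdays(date(2013, 6, 3), n)
    assert classify_completion(dates) == expected
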