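"""Radiotherapy course assembly and dose estimation from delivery dates.

Weekday fraction dates are split into courses wherever consecutive
fractions are more than 30 days apart; each course gets a fraction count,
schedule label, completion status, and an estimated total dose in Gy from
the tiered fraction-count rule (no estimate under 5 fractions; 66 Gy cap).
"""

from datetime import date, timedelta

from claims2tx import assign_rt_dose, build_rt_courses


def weekdays(start, n):
    out, d = [], start
    while len(out) < n:
        if d.weekday() < 5:
            out.append(d)
        d += timedelta(days=1)
    return out


diagnosis = date(2013, 3, 1)
initial = weekdays(date(2013, 6, 3), 16)  # hypofractionated course
boost = weekdays(initial[-1] + timedelta(days=40), 5)  # later short course

for course in build_rt_courses(initial + boost, diagnosis):
    print(
        f"{course.start} .. {course.end}: {course.n_fractions:2d} fractions, "
        f"{course.schedule:16s} {course.completion:10s} "
        f"estimated {course.estimated_total_gy} Gy"
    )

print("\nTiered dose rule examples:")
for n in (4, 12, 16, 20, 25, 40):
    print(f"  {n:2d} fractions -> {assign_rt_dose(n)} Gy")

# 16 fractions match the hypofractionated schedule (2.66 Gy each -> 42.6 Gy);
# the 5-fraction run after a >30-day gap is its own (incomplete) course at
# 2.67 Gy per fraction; 40 fractions would exceed the 66 Gy cap and are
# assigned 66 Gy.
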