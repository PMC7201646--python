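"""Hand-built 25-person toy database with hand-computed cohort expectations.

Every person is designed to exercise one branch of the cohort logic; the
EXPECTED_* constants below were worked out by hand from the inclusion rules
(index on 2015-06-01 unless stated, observation 2012-01-01..2017-12-31).

person  design                                                          T2  T1  label
p01     inpatient AF; inpatient stroke day 10; diabetes 2013-07-01      y   y   1
p02     two outpatient AF (6-1, 7-1); diabetes at day +5 (future)       y   y   0
p03     AF + ECG 10 days prior; OUTPATIENT stroke day 10 (age 75)       y   y   0
p04     inpatient AF; ER stroke day 365 (age 85)                        y   y   1
p05     inpatient AF; inpatient stroke day 0 only (age 68):
        excluded — a stroke on the index date counts as prior           -   -
p06     inpatient AF; inpatient stroke day 100 (age 50)                 y   -   1
p07     inpatient AF (age 98)                                           y   -   0
p08     male, inpatient AF                                              -   -
p09     single outpatient AF only                                       -   -
p10     AF + ECG 47 days prior (window is 30)                           -   -
p11     two same-day outpatient AF records                              -   -
p12     inpatient AF, observation starts 2014-06-01 (365d washout)      -   -
p13     inpatient AF; prior stroke 2014-01-01                           -   -
p14     inpatient AF; prior anticoagulant 2015-02-21                    -   -
p15     inpatient AF; anticoagulant ON index day                        -   -
p16     inpatient AF; AC day 100, no stroke; liver disease history      y   y   0   (censored out)
p17     inpatient AF; stroke day 50, AC day 100; CHF+liver history      y   y   1   (kept, censor 100)
p18     inpatient AF; AC day 100, stroke day 200                        y   y   1   (censored out)
p19     inpatient AF; inpatient stroke day 366 (outside window)         y   y   0
p20     two outpatient AF; AC day 30 (age 60)                           y   -   0   (censored out)
p21     AF + ECG on index day                                           y   y   0
p22     inpatient AF (age 95, upper T1 bound)                           y   y   0
p23     inpatient AF (age 65, lower T1 bound)                           y   y   0
p24     outpatient AF 2014-03-01 + inpatient AF 2015-06-01:
        index 2014-03-01 via two_records (790d washout, age 69)         y   y   0
p25     inpatient AF, observation ends day 61 after index               y   y   0
"""

from __future__ import annotations

import pandas as pd

from strokevalnet.core import LongitudinalDatabase

AF = "atrial_fibrillation:000"
AF2 = "atrial_fibrillation:001"
ECG = "ecg:000"
STROKE = "stroke:000"
AC = "anticoagulant:000"
DIABETES = "diabetes:000"
CHF = "congestive_heart_failure:000"
LIVER = "liver_disease:000"

INDEX = "2015-06-01"

EXPECTED_ATTRITION_T2 = {
    "persons": 25,
    "index_found": 22,
    "sex": 21,
    "age": 21,
    "washout": 20,
    "no_prior_stroke": 18,
    "no_prior_anticoagulant": 16,
}
EXPECTED_ATTRITION_T1 = {
    "persons": 25,
    "index_found": 22,
    "sex": 21,
    "age": 18,
    "washout": 17,
    "no_prior_stroke": 15,
    "no_prior_anticoagulant": 13,
}

EXPECTED_T2 = {
    "p01", "p02", "p03", "p04", "p06", "p07", "p16", "p17", "p18",
    "p19", "p20", "p21", "p22", "p23", "p24", "p25",
}
EXPECTED_T1 = EXPECTED_T2 - {"p06", "p07", "p20"}

#: person -> (label, event_day or None) in the all-ages population
EXPECTED_LABELS = {
    "p01": (1, 10), "p02": (0, None), "p03": (0, None), "p04": (1, 365),
    "p06": (1, 100), "p07": (0, None), "p16": (0, None),
    "p17": (1, 50), "p18": (1, 200), "p19": (0, None), "p20": (0, None),
    "p21": (0, None), "p22": (0, None), "p23": (0, None), "p24": (0, None),
    "p25": (0, None),
}

EXPECTED_SENSITIVITY_REMOVED = {"p16", "p18", "p20"}

EXPECTED_RULES = {
    "p01": "inpatient", "p02": "two_records", "p03": "ecg_prior",
    "p20": "two_records", "p21": "ecg_prior", "p24": "two_records",
}
EXPECTED_INDEX_DATES = {"p24": "2014-03-01"}


def build_toy_database() -> LongitudinalDatabase:
    persons: list[tuple] = []
    periods: list[tuple] = []
    events: list[tuple] = []

    def person(pid, sex="female", yob=1945, start="2012-01-01", end="2017-12-31"):
        persons.append((pid, sex, yob))
        periods.append((pid, pd.Timestamp(start), pd.Timestamp(end)))

    def ev(pid, date, code, domain="condition", ctx="outpatient"):
        events.append((pid, pd.Timestamp(date), code, domain, ctx))

    person("p01")
    ev("p01", INDEX, AF, ctx="inpatient")
    ev("p01", "2015-06-11", STROKE, ctx="inpatient")
    ev("p01", "2013-07-01", DIABETES)

    person("p02")
    ev("p02", INDEX, AF)
    ev("p02", "2015-07-01", AF)
    ev("p02", "2015-06-06", DIABETES)  # day +5: must not leak into features

    person("p03", yob=1940)
    ev("p03", INDEX, AF)
    ev("p03", "2015-05-22", ECG, domain="procedure")
    ev("p03", "2015-06-11", STROKE, ctx="outpatient")

    person("p04", yob=1930)
    ev("p04", INDEX, AF, ctx="inpatient")
    ev("p04", "2016-05-31", STROKE, ctx="er")  # day 365, closed window end

    person("p05", yob=1947)
    ev("p05", INDEX, AF, ctx="inpatient")
    ev("p05", INDEX, STROKE, ctx="inpatient")  # day 0: window starts at day 1

    person("p06", yob=1965)
    ev("p06", INDEX, AF, ctx="inpatient")
    ev("p06", "2015-09-09", STROKE, ctx="inpatient")  # day 100

    person("p07", yob=1917)
    ev("p07", INDEX, AF, ctx="inpatient")

    person("p08", sex="male")
    ev("p08", INDEX, AF, ctx="inpatient")

    person("p09")
    ev("p09", INDEX, AF)

    person("p10")
    ev("p10", INDEX, AF)
    ev("p10", "2015-04-15", ECG, domain="procedure")  # 47 days prior

    person("p11")
    ev("p11", INDEX, AF)
    ev("p11", INDEX, AF2)  # same calendar date: does not qualify

    person("p12", start="2014-06-01")
    ev("p12", INDEX, AF, ctx="inpatient")

    person("p13")
    ev("p13", INDEX, AF, ctx="inpatient")
    ev("p13", "2014-01-01", STROKE)

    person("p14")
    ev("p14", INDEX, AF, ctx="inpatient")
    ev("p14", "2015-02-21", AC, domain="drug")

    person("p15")
    ev("p15", INDEX, AF, ctx="inpatient")
    ev("p15", INDEX, AC, domain="drug")  # offset 0 counts as prior

    person("p16")
    ev("p16", INDEX, AF, ctx="inpatient")
    ev("p16", "2015-09-09", AC, domain="drug")  # day 100
    ev("p16", "2014-05-01", LIVER)

    person("p17")
    ev("p17", INDEX, AF, ctx="inpatient")
    ev("p17", "2015-07-21", STROKE, ctx="inpatient")  # day 50
    ev("p17", "2015-09-09", AC, domain="drug")  # day 100, after the stroke
    ev("p17", "2014-01-01", CHF)
    ev("p17", "2014-02-01", LIVER)

    person("p18")
    ev("p18", INDEX, AF, ctx="inpatient")
    ev("p18", "2015-09-09", AC, domain="drug")  # day 100
    ev("p18", "2015-12-18", STROKE, ctx="inpatient")  # day 200, after the AC

    person("p19")
    ev("p19", INDEX, AF, ctx="inpatient")
    ev("p19", "2016-06-01", STROKE, ctx="inpatient")  # day 366

    person("p20", yob=1955)
    ev("p20", INDEX, AF)
    ev("p20", "2015-07-01", AF)
    ev("p20", "2015-07-01", AC, domain="drug")  # day 30

    person("p21")
    ev("p21", INDEX, AF)
    ev("p21", INDEX, ECG, domain="procedure")  # ECG on the index day qualifies

    person("p22", yob=1920)
    ev("p22", INDEX, AF, ctx="inpatient")

    person("p23", yob=1950)
    ev("p23", INDEX, AF, ctx="inpatient")

    person("p24")
    ev("p24", "2014-03-01", AF)
    ev("p24", INDEX, AF, ctx="inpatient")

    person("p25", end="2015-08-01")
    ev("p25", INDEX, AF, ctx="inpatient")

    return LongitudinalDatabase(
        "toy",
        pd.DataFrame(persons, columns=["person_id", "sex", "year_of_birth"]),
        pd.DataFrame(periods, columns=["person_id", "start_date", "end_date"]),
        pd.DataFrame(events, columns=["person_id", "date", "code", "domain", "visit_context"]),
    )
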