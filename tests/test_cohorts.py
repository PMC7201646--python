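"""Index rules, inclusion/exclusion, outcome window, and censoring."""

import pandas as pd
import pytest

import strokevalnet as sv

from _toydb import (
    EXPECTED_ATTRITION_T1,
    EXPECTED_ATTRITION_T2,
    EXPECTED_INDEX_DATES,
    EXPECTED_LABELS,
    EXPECTED_RULES,
    EXPECTED_SENSITIVITY_REMOVED,
    EXPECTED_T1,
    EXPECTED_T2,
)


@pytest.fixture(scope="module")
def t2_labeled(toy_db, registry):
    entries = sv.build_target_cohort(toy_db, sv.T2, registry)
    return sv.assign_outcome_labels(toy_db, entries, registry)


def test_index_rules_on_designed_persons(toy_db, registry):
    for pid, rule in EXPECTED_RULES.items():
        found = sv.find_index_date(toy_db, pid, registry)
        assert found is not None, pid
        assert found[1] == rule, pid
    for pid, date in EXPECTED_INDEX_DATES.items():
        assert sv.find_index_date(toy_db, pid, registry)[0] == pd.Timestamp(date)


@pytest.mark.parametrize("pid", ["p09", "p10", "p11"])
def test_no_qualifying_rule_yields_none(toy_db, registry, pid):
    # single outpatient record / ECG outside 30 days / duplicate same-day records
    assert sv.find_index_date(toy_db, pid, registry) is None


def test_attrition_counts_match_hand_computation(toy_db, registry):
    _, att2 = sv.build_target_cohort(toy_db, sv.T2, registry, return_attrition=True)
    _, att1 = sv.build_target_cohort(toy_db, sv.T1, registry, return_attrition=True)
    assert att2 == EXPECTED_ATTRITION_T2
    assert att1 == EXPECTED_ATTRITION_T1


def test_cohort_membership_and_subset(toy_db, registry):
    t2 = sv.build_target_cohort(toy_db, sv.T2, registry)
    t1 = sv.build_target_cohort(toy_db, sv.T1, registry)
    assert set(t2["person_id"]) == EXPECTED_T2
    assert set(t1["person_id"]) == EXPECTED_T1
    assert set(t1["person_id"]) <= set(t2["person_id"])


def test_outcome_labels_and_event_days(t2_labeled):
    got = {
        row.person_id: (row.label, None if pd.isna(row.event_day) else int(row.event_day))
        for row in t2_labeled.itertuples()
    }
    assert got == EXPECTED_LABELS


def test_time_at_risk_window_is_closed_1_to_365(toy_db, registry):
    """Day 0 does not count (window starts at day 1); day 365 does; day 366 not.

    Checked directly on the labeller: a stroke on the index date also excludes
    the person from the cohort (it counts as prior), so the day-0 case cannot
    be reached through the full pipeline.
    """
    entries = pd.DataFrame(
        {
            "person_id": ["p05", "p04", "p19"],
            "cohort_name": "T2",
            "index_date": pd.Timestamp("2015-06-01"),
            "age_at_index": [68, 85, 70],
            "qualifying_rule": "inpatient",
        }
    )
    labeled = sv.assign_outcome_labels(toy_db, entries, registry).set_index("person_id")
    assert labeled.loc["p05", "label"] == 0  # stroke at offset 0 only
    assert labeled.loc["p04", "label"] == 1 and int(labeled.loc["p04", "event_day"]) == 365
    assert labeled.loc["p19", "label"] == 0  # stroke at offset 366


def test_censoring_examples(toy_db, registry, t2_labeled):
    censored = sv.apply_censoring(t2_labeled, toy_db, registry)
    removed = set(t2_labeled["person_id"]) - set(censored["person_id"])
    assert removed == EXPECTED_SENSITIVITY_REMOVED
    kept = censored.set_index("person_id")
    # stroke (day 50) before anticoagulant (day 100): retained with label intact
    assert kept.loc["p17", "label"] == 1
    assert int(kept.loc["p17", "event_day"]) == 50
    assert int(kept.loc["p17", "censor_day"]) == 100
    # untreated entries unchanged, no censor day
    assert pd.isna(kept.loc["p01", "censor_day"])


def test_exclusion_soundness_brute_force(toy_db, registry):
    """No cohort member has any exclusion-set event on or before index."""
    entries = sv.build_target_cohort(toy_db, sv.T2, registry)
    excl_codes = registry.codes("prior_stroke_tia") | registry.codes("anticoagulant")
    for row in entries.itertuples():
        person_events = toy_db.events[toy_db.events["person_id"] == row.person_id]
        prior = person_events[
            person_events["code"].isin(excl_codes) & (person_events["date"] <= row.index_date)
        ]
        assert prior.empty, row.person_id


def test_subset_properties_on_generated_database(gen_db, registry):
    db, _ = gen_db
    t2 = sv.build_target_cohort(db, sv.T2, registry)
    t1 = sv.build_target_cohort(db, sv.T1, registry)
    assert set(t1["person_id"]) <= set(t2["person_id"])
    labeled = sv.assign_outcome_labels(db, t2, registry)
    censored = sv.apply_censoring(labeled, db, registry)
    assert set(censored["person_id"]) <= set(labeled["person_id"])
    # retained treated entries all had their stroke on or before the anticoagulant
    treated = censored[censored["censor_day"].notna()]
    assert (treated["label"] == 1).all()
    assert (treated["event_day"] <= treated["censor_day"]).all()


def test_labels_match_ground_truth_emissions(gen_db, registry):
    """Labelled positives are exactly the persons with an emitted stroke in-window."""
    db, truth = gen_db
    labeled = sv.assign_outcome_labels(db, sv.build_target_cohort(db, sv.T2, registry), registry)
    merged = labeled.merge(truth[["person_id", "emitted_stroke_day"]], on="person_id")
    expected = merged["emitted_stroke_day"].notna() & merged["emitted_stroke_day"].between(1, 365)
    assert (merged["label"] == expected.astype(int)).all()
    hit = merged[merged["label"] == 1]
    assert (hit["event_day"].astype(float) == hit["emitted_stroke_day"]).all()
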