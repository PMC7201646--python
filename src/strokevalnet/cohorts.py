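"""Target populations, outcome labelling, and anticoagulant censoring.

Two target populations of women newly diagnosed with atrial fibrillation (AF):

* **T1** — aged 65-95 at index;
* **T2** — all ages;

both requiring a qualifying AF presentation (two AF records on distinct dates,
one inpatient AF record, or one AF record with an ECG within the 30 days
prior), at least 730 days of continuous pre-index observation, and no stroke
or anticoagulant record on or before the index date.

The outcome is an ischemic or hemorrhagic stroke recorded with an inpatient or
ER visit at a day offset in the closed window [1, 365] after index. The
sensitivity analysis censors at the first anticoagulant in that window: any
patient with an anticoagulant during time-at-risk is removed unless their
stroke occurred on or before the anticoagulant day.

Conventions (day-granular, both ends inclusive unless stated):

* the index is the *earliest* AF event date participating in a satisfied rule;
  for the two-records rule the first record is the index;
* the two qualifying AF records must fall on distinct calendar dates;
* the ECG window is [index-30, index];
* rule priority when several rules share the earliest date:
  inpatient > two_records > ecg_prior;
* washout requires one observation period covering [index-730, index];
* patients whose observation ends before day 365 keep their observed label.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .concepts import ConceptSetRegistry, builtin_concept_sets
from .core import LongitudinalDatabase

ENTRY_COLUMNS = ("person_id", "cohort_name", "index_date", "age_at_index", "qualifying_rule")
LABEL_COLUMNS = ENTRY_COLUMNS + ("label", "event_day", "censor_day")

QUALIFYING_RULES = ("two_records", "inpatient", "ecg_prior")

WASHOUT_DAYS = 730
TAR_START = 1
TAR_END = 365
ECG_WINDOW_DAYS = 30


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Inclusion rules for one target population (female-only in this study)."""

    name: str
    age_min: int | None = None
    age_max: int | None = None
    washout_days: int = WASHOUT_DAYS
    sex_required: str = "female"
    exclusion_sets: tuple[str, ...] = ("prior_stroke_tia", "anticoagulant")


T1 = CohortSpec("T1", age_min=65, age_max=95)
T2 = CohortSpec("T2")

_SPECS = {"T1": T1, "T2": T2}


def cohort_spec(name: str) -> CohortSpec:
    if name not in _SPECS:
        raise ValueError(f"unknown cohort {name!r}; available: {', '.join(sorted(_SPECS))}")
    return _SPECS[name]


def _index_table(db: LongitudinalDatabase, registry: ConceptSetRegistry) -> pd.DataFrame:
    """Per-person index date and qualifying rule, vectorised over the database.

    Returns columns ``person_id, index_date, qualifying_rule`` for persons
    satisfying at least one rule.
    """
    events = db.events
    af = events[events["code"].isin(registry.codes("atrial_fibrillation"))]
    if af.empty:
        return pd.DataFrame(columns=["person_id", "index_date", "qualifying_rule"])

    candidates: dict[str, pd.Series] = {}

    first_af = af.groupby("person_id")["date"].min()
    n_distinct = af.drop_duplicates(["person_id", "date"]).groupby("person_id").size()
    candidates["two_records"] = first_af[n_distinct[n_distinct >= 2].index]

    inpt = af[af["visit_context"] == "inpatient"]
    if not inpt.empty:
        candidates["inpatient"] = inpt.groupby("person_id")["date"].min()

    ecg_events = events[events["code"].isin(registry.codes("ecg"))]
    if not ecg_events.empty:
        pairs = af[["person_id", "date"]].merge(
            ecg_events[["person_id", "date"]], on="person_id", suffixes=("", "_ecg")
        )
        gap = (pairs["date"] - pairs["date_ecg"]).dt.days
        hit = pairs[(gap >= 0) & (gap <= ECG_WINDOW_DAYS)]
        if not hit.empty:
            candidates["ecg_prior"] = hit.groupby("person_id")["date"].min()

    table = pd.DataFrame(candidates)
    if table.empty:
        return pd.DataFrame(columns=["person_id", "index_date", "qualifying_rule"])
    index_date = table.min(axis=1)
    rule = pd.Series("", index=table.index)
    for name in ("ecg_prior", "two_records", "inpatient"):  # ascending priority
        if name in table:
            rule = rule.mask(table[name] == index_date, name)
    out = pd.DataFrame(
        {"person_id": table.index, "index_date": index_date.values, "qualifying_rule": rule.values}
    )
    return out.reset_index(drop=True)


def find_index_date(
    db: LongitudinalDatabase, person_id: str, registry: ConceptSetRegistry | None = None
):
    """Index date and qualifying rule for one person, or ``None`` if no rule holds."""
    registry = registry or builtin_concept_sets()
    if person_id not in set(db.persons["person_id"]):
        raise KeyError(f"unknown person_id {person_id!r}")
    sub = LongitudinalDatabase(
        db.name,
        db.persons[db.persons["person_id"] == person_id],
        db.periods[db.periods["person_id"] == person_id],
        db.events[db.events["person_id"] == person_id],
    )
    table = _index_table(sub, registry)
    if table.empty:
        return None
    row = table.iloc[0]
    return row["index_date"], row["qualifying_rule"]


def build_target_cohort(
    db: LongitudinalDatabase,
    spec: CohortSpec,
    registry: ConceptSetRegistry | None = None,
    return_attrition: bool = False,
):
    """Apply index rules, sex, age bounds, washout and prior-event exclusions.

    Returns an entry frame with columns ``person_id, cohort_name, index_date,
    age_at_index, qualifying_rule`` (and, when ``return_attrition`` is set, a
    dict of persons surviving each successive inclusion step).
    """
    registry = registry or builtin_concept_sets()
    attrition: dict[str, int] = {"persons": len(db.persons)}

    entries = _index_table(db, registry)
    attrition["index_found"] = len(entries)

    entries = entries.merge(db.persons, on="person_id")
    entries = entries[entries["sex"] == spec.sex_required]
    attrition["sex"] = len(entries)

    entries["age_at_index"] = entries["index_date"].dt.year - entries["year_of_birth"]
    if spec.age_min is not None:
        entries = entries[entries["age_at_index"] >= spec.age_min]
    if spec.age_max is not None:
        entries = entries[entries["age_at_index"] <= spec.age_max]
    attrition["age"] = len(entries)

    merged = entries[["person_id", "index_date"]].merge(db.periods, on="person_id")
    covering = merged[
        (merged["start_date"] <= merged["index_date"] - pd.Timedelta(days=spec.washout_days))
        & (merged["end_date"] >= merged["index_date"])
    ]
    entries = entries[entries["person_id"].isin(covering["person_id"])]
    attrition["washout"] = len(entries)

    for set_name, step in zip(spec.exclusion_sets, ("no_prior_stroke", "no_prior_anticoagulant")):
        excl_events = db.events[db.events["code"].isin(registry.codes(set_name))]
        hit = entries[["person_id", "index_date"]].merge(excl_events, on="person_id")
        prior = hit[hit["date"] <= hit["index_date"]]["person_id"]
        entries = entries[~entries["person_id"].isin(set(prior))]
        attrition[step] = len(entries)

    entries = entries.assign(cohort_name=spec.name)[list(ENTRY_COLUMNS)]
    entries = entries.sort_values("person_id").reset_index(drop=True)
    if return_attrition:
        return entries, attrition
    return entries


def _first_offset_in_tar(
    db: LongitudinalDatabase,
    entries: pd.DataFrame,
    codes: frozenset[str],
    contexts: tuple[str, ...] | None,
) -> pd.Series:
    """Earliest day offset in [TAR_START, TAR_END] of a matching event, per person."""
    subset = db.events[db.events["code"].isin(codes)]
    if contexts is not None:
        subset = subset[subset["visit_context"].isin(contexts)]
    hit = entries[["person_id", "index_date"]].merge(subset, on="person_id")
    offset = (hit["date"] - hit["index_date"]).dt.days
    hit = hit[(offset >= TAR_START) & (offset <= TAR_END)]
    offset = offset[hit.index]
    return offset.groupby(hit["person_id"]).min()


def assign_outcome_labels(
    db: LongitudinalDatabase, entries: pd.DataFrame, registry: ConceptSetRegistry | None = None
) -> pd.DataFrame:
    """Label = 1 iff an inpatient/ER stroke occurs at offset 1..365 from index.

    ``event_day`` is the earliest qualifying offset; ``censor_day`` is filled
    by :func:`apply_censoring` and starts missing.
    """
    registry = registry or builtin_concept_sets()
    first_stroke = _first_offset_in_tar(
        db, entries, registry.codes("stroke"), contexts=("inpatient", "er")
    )
    labeled = entries.copy()
    labeled["event_day"] = labeled["person_id"].map(first_stroke).astype("Int64")
    labeled["label"] = labeled["event_day"].notna().astype(int)
    labeled["censor_day"] = pd.array([pd.NA] * len(labeled), dtype="Int64")
    return labeled[list(LABEL_COLUMNS)]


def apply_censoring(
    labeled: pd.DataFrame, db: LongitudinalDatabase, registry: ConceptSetRegistry | None = None
) -> pd.DataFrame:
    """Censor at the first anticoagulant during time-at-risk.

    Entries with an anticoagulant at offset 1..365 are removed unless the
    stroke occurred on or before the anticoagulant day; retained treated
    entries get ``censor_day`` set, labels untouched.
    """
    registry = registry or builtin_concept_sets()
    first_ac = _first_offset_in_tar(db, labeled, registry.codes("anticoagulant"), contexts=None)
    ac = labeled["person_id"].map(first_ac).astype("Int64")
    stroke_first = (labeled["label"] == 1) & labeled["event_day"].notna() & (labeled["event_day"] <= ac)
    keep = ac.isna() | stroke_first
    out = labeled[keep].copy()
    out["censor_day"] = ac[keep]
    return out.reset_index(drop=True)
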