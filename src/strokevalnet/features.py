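"""Per-patient risk-factor feature vectors under the study missing-data policy.

A condition flag is 1 iff any event from its concept set occurs on or before
the index date (lifetime lookback); no record means the patient does not have
the condition. Smoking status and family history are imputed to 0 (never
smoker, no family history) when unrecorded, and the availability mask records
the imputation. Ethnicity, blood pressure, cholesterol ratio and the Townsend
deprivation score are structurally absent: they are dropped from validation
when missing from claims data, so they never appear as features.
"""

from __future__ import annotations

import dataclasses

import pandas as pd

from .concepts import ConceptSetRegistry, UnknownConceptSetError, builtin_concept_sets
from .core import LongitudinalDatabase


class FeatureExtractionError(RuntimeError):
    """A required predictor has no concept set in the registry."""


@dataclasses.dataclass(frozen=True)
class MissingDataPolicy:
    absent_condition_means_negative: bool = True
    impute_never_smoker: bool = True
    impute_no_family_history: bool = True
    drop_when_missing: tuple[str, ...] = (
        "ethnicity",
        "systolic_bp",
        "cholesterol_ratio",
        "townsend_score",
    )


DEFAULT_POLICY = MissingDataPolicy()

#: feature flag -> concept set resolving it (chf_or_liver_disease is derived).
FLAG_SETS: dict[str, str] = {
    "diabetes": "diabetes",
    "congestive_heart_failure": "congestive_heart_failure",
    "prior_stroke_tia": "prior_stroke_tia",
    "hypertension": "hypertension",
    "proteinuria": "proteinuria",
    "esrd_or_low_egfr": "esrd_or_low_egfr",
    "vascular_disease": "vascular_disease",
    "liver_disease": "liver_disease",
    "smoker": "smoking",
    "coronary_heart_disease": "coronary_heart_disease",
    "family_history_chf": "family_history_chf",
    "atrial_fibrillation": "atrial_fibrillation",
    "rheumatoid_arthritis": "rheumatoid_arthritis",
    "chronic_renal_disease": "chronic_renal_disease",
    "valvular_heart_disease": "valvular_heart_disease",
}

#: Flags emitted in features frames (liver_disease folds into chf_or_liver_disease).
FEATURE_FLAGS = (
    "diabetes",
    "congestive_heart_failure",
    "prior_stroke_tia",
    "hypertension",
    "proteinuria",
    "esrd_or_low_egfr",
    "vascular_disease",
    "chf_or_liver_disease",
    "smoker",
    "coronary_heart_disease",
    "family_history_chf",
    "atrial_fibrillation",
    "rheumatoid_arthritis",
    "chronic_renal_disease",
    "valvular_heart_disease",
)

_IMPUTABLE = ("smoker", "family_history_chf")


def extract_features(
    db: LongitudinalDatabase,
    entries: pd.DataFrame,
    registry: ConceptSetRegistry | None = None,
    policy: MissingDataPolicy = DEFAULT_POLICY,
) -> pd.DataFrame:
    """One feature vector per cohort entry.

    Columns: ``person_id``, ``age_years``, ``female`` (always 1 here), one
    binary column per flag in :data:`FEATURE_FLAGS`, and one ``avail_<flag>``
    marker per flag with values ``observed`` / ``imputed``.
    """
    registry = registry or builtin_concept_sets()

    raw: dict[str, pd.Series] = {}
    for flag, set_name in FLAG_SETS.items():
        try:
            codes = registry.codes(set_name)
        except UnknownConceptSetError as exc:
            raise FeatureExtractionError(
                f"no concept set for required predictor {flag!r} (set {set_name!r})"
            ) from exc
        subset = db.events[db.events["code"].isin(codes)]
        hit = entries[["person_id", "index_date"]].merge(subset, on="person_id")
        prior = hit[hit["date"] <= hit["index_date"]]
        raw[flag] = (
            entries["person_id"].isin(set(prior["person_id"])).astype(int).set_axis(entries.index)
        )

    out = pd.DataFrame(
        {
            "person_id": entries["person_id"],
            "age_years": entries["age_at_index"].astype(int),
            "female": 1,
        }
    )
    for flag in FEATURE_FLAGS:
        if flag == "chf_or_liver_disease":
            out[flag] = (raw["congestive_heart_failure"] | raw["liver_disease"]).astype(int)
        else:
            out[flag] = raw[flag]
    for flag in FEATURE_FLAGS:
        if flag in _IMPUTABLE:
            out[f"avail_{flag}"] = pd.Series("observed", index=out.index).mask(
                out[flag] == 0, "imputed"
            )
        else:
            out[f"avail_{flag}"] = "observed"
    return out.reset_index(drop=True)
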