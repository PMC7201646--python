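"""Score fixtures: worked examples, range, monotonicity, irrelevance."""

import itertools

import numpy as np
import pandas as pd
import pytest

import strokevalnet as sv
from strokevalnet.scores import MODEL_NAMES


def base_features(age, **flags):
    feats = {"person_id": "x", "age_years": age, "female": 1}
    for name in (
        "diabetes", "congestive_heart_failure", "prior_stroke_tia", "hypertension",
        "proteinuria", "esrd_or_low_egfr", "vascular_disease", "chf_or_liver_disease",
        "smoker", "coronary_heart_disease", "family_history_chf", "atrial_fibrillation",
        "rheumatoid_arthritis", "chronic_renal_disease", "valvular_heart_disease",
    ):
        feats[name] = 0
    feats.update(flags)
    return feats


def enumerate_scores(definition):
    """All flag combinations x one representative age per band."""
    covs = [name for name, _ in definition.covariates]
    ages = [band.min_age for band in definition.age_bands]
    for age in ages:
        for bits in itertools.product([0, 1], repeat=len(covs)):
            feats = base_features(age, female=0)
            feats.update(dict(zip(covs, bits)))
            yield feats, sv.compute_score(definition, feats)


def test_registry_has_exactly_five_models(definitions):
    assert sorted(definitions) == sorted(MODEL_NAMES)


def test_covariate_membership(definitions):
    chads2 = {name for name, _ in definitions["CHADS2"].covariates}
    assert chads2 == {"congestive_heart_failure", "hypertension", "diabetes", "prior_stroke_tia"}
    assert {b.min_age for b in definitions["CHADS2"].age_bands} == {0, 75}
    vasc = {name for name, _ in definitions["CHA2DS2VASc"].covariates}
    assert "female" in vasc and "vascular_disease" in vasc
    assert "townsend_score" in definitions["QStroke"].excluded_predictors
    assert "systolic_bp" in definitions["Framingham"].excluded_predictors


@pytest.mark.parametrize(
    "model,age,flags,expected",
    [
        ("CHADS2", 50, {}, 0),
        ("CHADS2", 80, dict(congestive_heart_failure=1, hypertension=1, diabetes=1), 4),
        ("CHA2DS2VASc", 40, {}, 1),  # female point only
        (
            "CHA2DS2VASc",
            80,
            dict(congestive_heart_failure=1, hypertension=1, diabetes=1, vascular_disease=1),
            7,
        ),
    ],
)
def test_worked_examples(definitions, model, age, flags, expected):
    result = sv.compute_score(definitions[model], base_features(age, **flags))
    assert result.raw_score == expected
    assert result.in_range


@pytest.mark.parametrize("model", MODEL_NAMES)
def test_exhaustive_enumeration_range_and_endpoints(definitions, model):
    definition = definitions[model]
    lo, hi = definition.valid_range
    values = [r.raw_score for _, r in enumerate_scores(definition)]
    assert all(r.in_range for _, r in enumerate_scores(definition))
    assert min(values) == pytest.approx(lo, abs=1e-9)
    assert max(values) == pytest.approx(hi, abs=1e-9)
    if definition.output_kind == "integer_points":
        assert all(float(v).is_integer() for v in values)


@pytest.mark.parametrize("model", MODEL_NAMES)
def test_monotonicity_in_flags_and_age(definitions, model):
    definition = definitions[model]
    covs = [name for name, _ in definition.covariates]
    for feats, result in enumerate_scores(definition):
        for cov in covs:
            if feats[cov] == 0:
                bumped = dict(feats, **{cov: 1})
                assert sv.compute_score(definition, bumped).raw_score >= result.raw_score
    band_weights = [b.weight for b in sorted(definition.age_bands, key=lambda b: b.min_age)]
    assert band_weights == sorted(band_weights)  # older never scores lower


@pytest.mark.parametrize("model", MODEL_NAMES)
def test_irrelevant_predictors_do_not_change_score(definitions, model):
    definition = definitions[model]
    covs = {name for name, _ in definition.covariates}
    feats = base_features(72, diabetes=1, hypertension=1)
    baseline = sv.compute_score(definition, feats).raw_score
    for other in set(base_features(72)) - covs - {"person_id", "age_years"}:
        perturbed = dict(feats, **{other: 1 - feats[other]})
        assert sv.compute_score(definition, perturbed).raw_score == baseline, other


def test_vectorised_scores_match_scalar(definitions, gen_db, registry):
    db, _ = gen_db
    entries = sv.build_target_cohort(db, sv.T2, registry).head(200)
    feats = sv.extract_features(db, entries, registry)
    for definition in definitions.values():
        vec = sv.compute_scores(definition, feats)
        scalar = [sv.compute_score(definition, row).raw_score for row in feats.to_dict("records")]
        assert np.allclose(vec.to_numpy(), scalar)


def test_cohort_scores_never_include_stroke_points(definitions, gen_db, registry):
    """prior_stroke_tia is 0 in-cohort, so CHADS2 <= 4 and CHA2DS2VASc <= 7."""
    db, _ = gen_db
    entries = sv.build_target_cohort(db, sv.T2, registry)
    feats = sv.extract_features(db, entries, registry)
    assert sv.compute_scores(definitions["CHADS2"], feats).max() <= 4
    assert sv.compute_scores(definitions["CHA2DS2VASc"], feats).max() <= 7
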