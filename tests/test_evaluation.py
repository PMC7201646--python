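"""AUROC, DeLong intervals, recalibration, and calibration deciles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit, logit

import strokevalnet as sv
from strokevalnet.evaluation import delong_variance


def brute_force_auroc(scores, labels):
    """O(n^2) pairwise concordance with ties credited one half."""
    scores = np.asarray(scores, dtype=float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


@pytest.mark.parametrize(
    "scores,labels,expected",
    [
        ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),  # perfect separation
        ([1.0, 1.0, 1.0, 1.0], [1, 0, 1, 0], 0.5),  # all pairs tied
        ([3, 1, 2, 2], [1, 0, 0, 1], 0.875),        # 3 concordant + 1 half-tie of 4 pairs
    ],
)
def test_auroc_examples(scores, labels, expected):
    assert sv.auroc(scores, labels) == pytest.approx(expected, abs=1e-12)


def test_auroc_single_class_is_error():
    with pytest.raises(sv.SingleClassError):
        sv.auroc([1.0, 2.0], [1, 1])


def test_auroc_matches_brute_force_on_tied_instances():
    rng = np.random.default_rng(42)
    for _ in range(30):
        n = int(rng.integers(4, 120))
        scores = rng.integers(0, 5, n).astype(float)  # heavy ties
        labels = rng.integers(0, 2, n)
        if labels.sum() in (0, n):
            continue
        assert sv.auroc(scores, labels) == pytest.approx(
            brute_force_auroc(scores, labels), abs=1e-12
        )


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(st.integers(-50, 50), min_size=4, max_size=60),
    st.data(),
)
def test_auroc_invariant_under_monotone_transform(raw, data):
    # tenth-point grid: coarse enough that exp() keeps distinct values distinct
    scores = [x / 10.0 for x in raw]
    labels = data.draw(
        st.lists(st.integers(0, 1), min_size=len(scores), max_size=len(scores))
    )
    if sum(labels) in (0, len(labels)):
        return
    base = sv.auroc(scores, labels)
    transformed = np.exp(0.5 * np.asarray(scores)) + 3.0  # strictly increasing
    assert sv.auroc(transformed, labels) == pytest.approx(base, abs=1e-12)


def test_ci_rule_boundary():
    rng = np.random.default_rng(0)
    for n_pos, want_ci in [(999, True), (1000, False), (1500, False)]:
        scores = np.concatenate([rng.normal(1, 1, n_pos), rng.normal(0, 1, 2000)])
        labels = np.concatenate([np.ones(n_pos, int), np.zeros(2000, int)])
        ci = sv.auroc_ci(scores, labels)
        assert (ci is not None) is want_ci


def test_ci_truncated_on_perfect_separation():
    ci = sv.auroc_ci([4.0, 3.0, 1.0, 0.5], [1, 1, 0, 0])
    assert ci[1] == 1.0


def test_delong_matches_stratified_bootstrap():
    rng = np.random.default_rng(3)
    pos = rng.normal(0.8, 1.0, 30)
    neg = rng.normal(0.0, 1.0, 300)
    scores = np.concatenate([pos, neg])
    labels = np.concatenate([np.ones(30, int), np.zeros(300, int)])
    auc, var = delong_variance(scores, labels)
    boot = np.empty(2000)
    for b in range(2000):
        bp = pos[rng.integers(0, 30, 30)]
        bn = neg[rng.integers(0, 300, 300)]
        boot[b] = brute_force_auroc(
            np.concatenate([bp, bn]), labels
        )
    assert np.sqrt(var) == pytest.approx(boot.std(ddof=1), abs=0.015)


def test_delong_agrees_with_sklearn_point_estimate(gen_db, registry, definitions):
    sklearn = pytest.importorskip("sklearn.metrics")
    db, _ = gen_db
    labeled = sv.assign_outcome_labels(db, sv.build_target_cohort(db, sv.T2, registry), registry)
    feats = sv.extract_features(db, labeled, registry)
    scores = sv.compute_scores(definitions["CHA2DS2VASc"], feats)
    labels = labeled["label"].to_numpy()
    assert sv.auroc(scores, labels) == pytest.approx(
        sklearn.roc_auc_score(labels, scores), abs=1e-12
    )


def test_recalibration_constant_scores_closed_form():
    labels = np.array([1] * 10 + [0] * 90)
    fit = sv.fit_recalibration(np.full(100, 2.5), labels)
    assert fit.gradient == 0.0
    assert fit.intercept == pytest.approx(logit(0.10), abs=1e-9)
    assert fit.converged


def test_recalibration_mean_risk_equals_observed_rate():
    rng = np.random.default_rng(1)
    scores = rng.integers(0, 7, 5000).astype(float)
    labels = (rng.random(5000) < expit(-3 + 0.4 * scores)).astype(int)
    fit = sv.fit_recalibration(scores, labels)
    risks = sv.recalibrated_risk(fit, scores)
    assert risks.mean() == pytest.approx(labels.mean(), abs=1e-8)


def test_recalibration_parameter_recovery():
    rng = np.random.default_rng(2)
    scores = rng.uniform(0, 8, 20000)
    labels = (rng.random(20000) < expit(-3 + 0.5 * scores)).astype(int)
    fit = sv.fit_recalibration(scores, labels)
    assert fit.converged
    assert abs(fit.intercept - (-3.0)) <= 3 * fit.intercept_se
    assert abs(fit.gradient - 0.5) <= 3 * fit.gradient_se


def test_recalibration_detects_complete_separation():
    scores = np.array([0.0, 1.0, 2.0, 5.0, 6.0, 7.0])
    labels = np.array([0, 0, 0, 1, 1, 1])
    assert not sv.fit_recalibration(scores, labels).converged


def test_recalibration_preserves_auroc(gen_db, registry, definitions):
    db, _ = gen_db
    labeled = sv.assign_outcome_labels(db, sv.build_target_cohort(db, sv.T2, registry), registry)
    feats = sv.extract_features(db, labeled, registry)
    scores = sv.compute_scores(definitions["ATRIA"], feats).to_numpy()
    labels = labeled["label"].to_numpy()
    fit = sv.fit_recalibration(scores, labels)
    risks = sv.recalibrated_risk(fit, scores)
    assert sv.auroc(risks, labels) == pytest.approx(sv.auroc(scores, labels), abs=1e-12)


def test_deciles_conserve_counts_and_sizes():
    rng = np.random.default_rng(4)
    risks = rng.random(1037)
    labels = (rng.random(1037) < risks).astype(int)
    deciles = sv.calibration_deciles(risks, labels)
    assert deciles["n"].sum() == 1037
    assert deciles["n"].max() - deciles["n"].min() <= 1
    counts = (deciles["n"] * deciles["observed_fraction"]).round().astype(int)
    assert counts.sum() == labels.sum()


def test_deciles_stable_tie_handling():
    deciles = sv.calibration_deciles(np.full(20, 0.3), np.zeros(20, int))
    assert list(deciles["n"]) == [2] * 10


def test_deciles_require_ten_patients():
    with pytest.raises(ValueError):
        sv.calibration_deciles(np.arange(9) / 9.0, np.zeros(9, int))


def test_evaluate_model_composition(gen_db, registry, definitions):
    db, _ = gen_db
    result = sv.evaluate_model(definitions["CHA2DS2VASc"], db, "T1", registry=registry)
    assert 0.0 <= result.auroc <= 1.0
    assert (result.auroc_ci is not None) == (result.outcome_count < 1000)
    assert result.outcome_rate == pytest.approx(result.outcome_count / result.n)
    assert result.deciles["n"].sum() == result.n
    sens = sv.evaluate_model(definitions["CHA2DS2VASc"], db, "T1", sensitivity=True, registry=registry)
    assert sens.n <= result.n
    assert sens.population == "T1_sensitivity"


def test_latent_risk_dominates_fixture_scores(gen_db_untreated, registry, definitions):
    """The generator's latent risk is the Bayes-optimal ranker: it should beat
    every fixture score on the same cohort."""
    db, truth = gen_db_untreated
    labeled = sv.assign_outcome_labels(db, sv.build_target_cohort(db, sv.T2, registry), registry)
    feats = sv.extract_features(db, labeled, registry)
    labels = labeled["label"].to_numpy()
    merged = labeled.merge(truth[["person_id", "latent_risk"]], on="person_id")
    latent_auc = sv.auroc(merged["latent_risk"], labels)
    for definition in definitions.values():
        score_auc = sv.auroc(sv.compute_scores(definition, feats), labels)
        assert latent_auc >= score_auc - 0.01, definition.name
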