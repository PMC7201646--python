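"""Discrimination, conditional confidence intervals, recalibration, deciles.

* AUROC uses the rank (Mann-Whitney) formulation with ties credited 0.5, so
  tie semantics are exact rather than a trapezoid approximation.
* 95% confidence intervals use the DeLong asymptotic variance estimator and
  are reported only when the outcome count is below 1000 (the convention of
  the validation study this pipeline reproduces); they are truncated to [0,1].
* Recalibration fits outcome ~ intercept + gradient * score through the
  logistic link by maximum likelihood ("linear in the score on the log-odds
  scale"); an identity-link variant is available via ``link="identity"``.
* Calibration deciles are ten near-equal-count groups of patients ranked by
  recalibrated risk with stable tie-breaking, comparing mean predicted risk
  with the observed outcome fraction.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import norm, rankdata

from .cohorts import apply_censoring, assign_outcome_labels, build_target_cohort, cohort_spec
from .concepts import ConceptSetRegistry, builtin_concept_sets
from .core import LongitudinalDatabase
from .features import extract_features
from .scores import ScoreDefinition, compute_scores

CI_MAX_OUTCOMES = 1000
POPULATIONS = ("T1", "T2", "T1_sensitivity", "T2_sensitivity")


class SingleClassError(ValueError):
    """AUROC (and recalibration) are undefined when only one class is present."""


def _check_classes(labels: np.ndarray) -> tuple[int, int]:
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise SingleClassError("AUROC undefined: both outcome classes must be present")
    return n_pos, n_neg


def auroc(scores, labels) -> float:
    """Mann-Whitney concordance probability; tied pairs credited one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos, n_neg = _check_classes(labels)
    ranks = rankdata(scores)
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUROC, DeLong variance) via midrank structural components."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    m, n = _check_classes(labels)
    x = scores[labels == 1]
    y = scores[labels == 0]
    tz = rankdata(np.concatenate([x, y]))
    tx = rankdata(x)
    ty = rankdata(y)
    v01 = (tz[:m] - tx) / n          # per-positive components
    v10 = 1.0 - (tz[m:] - ty) / m    # per-negative components
    auc = float(v01.mean())
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    return auc, float(s01 / m + s10 / n)


def auroc_ci(scores, labels, ci_max_outcomes: int = CI_MAX_OUTCOMES, alpha: float = 0.05):
    """95% DeLong interval, or ``None`` when the outcome count reaches the cap."""
    labels = np.asarray(labels, dtype=int)
    n_pos, _ = _check_classes(labels)
    if n_pos >= ci_max_outcomes:
        return None
    auc, var = delong_variance(scores, labels)
    half = norm.ppf(1 - alpha / 2.0) * np.sqrt(var)
    return (float(max(0.0, auc - half)), float(min(1.0, auc + half)))


@dataclasses.dataclass(frozen=True)
class RecalibrationFit:
    intercept: float
    gradient: float
    converged: bool
    intercept_se: float | None = None
    gradient_se: float | None = None
    link: str = "logistic"


def fit_recalibration(scores, labels, link: str = "logistic") -> RecalibrationFit:
    """Refit intercept and gradient of a fixed score on a new population.

    Logistic link (default): maximum-likelihood fit of
    ``outcome ~ expit(intercept + gradient * score)``. Constant scores give a
    closed-form intercept-only fit; complete separation yields
    ``converged=False``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_classes(labels)

    if np.ptp(scores) == 0.0:
        rate = labels.mean()
        intercept = float(logit(rate)) if link == "logistic" else float(rate)
        return RecalibrationFit(intercept, 0.0, True, link=link)

    X = sm.add_constant(scores)
    if link == "identity":
        res = sm.OLS(labels, X).fit()
        return RecalibrationFit(
            float(res.params[0]),
            float(res.params[1]),
            True,
            float(res.bse[0]),
            float(res.bse[1]),
            link="identity",
        )
    if link != "logistic":
        raise ValueError(f"unknown link {link!r}; use 'logistic' or 'identity'")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(labels, X).fit(disp=0, maxiter=200)
    except Exception:  # perfect separation / singular design
        return RecalibrationFit(float("nan"), float("nan"), False)
    params = np.asarray(res.params, dtype=float)
    ok = bool(res.mle_retvals.get("converged", False)) and np.all(np.isfinite(params))
    if ok and np.max(np.abs(params)) > 1e3:
        ok = False  # quasi-separation: estimates diverging
    if not ok:
        return RecalibrationFit(float(params[0]), float(params[1]), False)
    bse = np.asarray(res.bse, dtype=float)
    return RecalibrationFit(
        float(params[0]), float(params[1]), True, float(bse[0]), float(bse[1])
    )


def recalibrated_risk(fit: RecalibrationFit, scores) -> np.ndarray:
    scores = np.asarray(scores, dtype=float)
    raw = fit.intercept + fit.gradient * scores
    if fit.link == "identity":
        return np.clip(raw, 0.0, 1.0)
    return expit(raw)


def calibration_deciles(risks, labels, n_groups: int = 10) -> pd.DataFrame:
    """Equal-count risk-ranked groups; stable tie-breaking by input order.

    Returns columns ``decile, n, mean_predicted, observed_fraction``; group
    sizes differ by at most one and partition the cohort.
    """
    risks = np.asarray(risks, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(risks) < n_groups:
        raise ValueError(f"need at least {n_groups} patients for {n_groups} groups")
    order = np.argsort(risks, kind="stable")
    rows = []
    for d, chunk in enumerate(np.array_split(order, n_groups), start=1):
        rows.append(
            {
                "decile": d,
                "n": len(chunk),
                "mean_predicted": float(risks[chunk].mean()),
                "observed_fraction": float(labels[chunk].mean()),
            }
        )
    return pd.DataFrame(rows)


@dataclasses.dataclass(frozen=True)
class NotEvaluable:
    """Structured marker for a (database, population, model) cell that cannot run."""

    model_name: str
    database_name: str
    population: str
    reason: str


@dataclasses.dataclass
class EvaluationResult:
    model_name: str
    database_name: str
    population: str
    n: int
    outcome_count: int
    outcome_rate: float
    auroc: float
    auroc_ci: tuple[float, float] | None
    recalibration: RecalibrationFit
    deciles: pd.DataFrame | None


def outcome_recordable(db: LongitudinalDatabase, registry: ConceptSetRegistry) -> bool:
    """Whether any stroke-coded event carries an inpatient or ER context."""
    strokes = db.events[db.events["code"].isin(registry.codes("stroke"))]
    return bool(strokes["visit_context"].isin(("inpatient", "er")).any())


def _parse_population(population: str) -> tuple[str, bool]:
    if population.endswith("_sensitivity"):
        return population[: -len("_sensitivity")], True
    return population, False


def labeled_cohort(
    db: LongitudinalDatabase,
    population: str,
    registry: ConceptSetRegistry | None = None,
) -> pd.DataFrame:
    """Cohort entries with labels for one population key (e.g. ``T1_sensitivity``)."""
    registry = registry or builtin_concept_sets()
    base, sensitivity = _parse_population(population)
    entries = build_target_cohort(db, cohort_spec(base), registry)
    labeled = assign_outcome_labels(db, entries, registry)
    if sensitivity:
        labeled = apply_censoring(labeled, db, registry)
    return labeled


def evaluate_scores(
    model_name: str,
    database_name: str,
    population: str,
    score_values: np.ndarray,
    labels: np.ndarray,
    ci_max_outcomes: int = CI_MAX_OUTCOMES,
    link: str = "logistic",
) -> EvaluationResult:
    """Metrics for one already-scored cohort (shared by single and network runs)."""
    labels = np.asarray(labels, dtype=int)
    n = len(labels)
    n_pos = int(labels.sum())
    auc = auroc(score_values, labels)
    ci = auroc_ci(score_values, labels, ci_max_outcomes=ci_max_outcomes)
    fit = fit_recalibration(score_values, labels, link=link)
    deciles = None
    if fit.converged and n >= 10:
        deciles = calibration_deciles(recalibrated_risk(fit, score_values), labels)
    return EvaluationResult(
        model_name=model_name,
        database_name=database_name,
        population=population,
        n=n,
        outcome_count=n_pos,
        outcome_rate=n_pos / n if n else float("nan"),
        auroc=auc,
        auroc_ci=ci,
        recalibration=fit,
        deciles=deciles,
    )


def evaluate_model(
    definition: ScoreDefinition,
    db: LongitudinalDatabase,
    population: str,
    sensitivity: bool = False,
    registry: ConceptSetRegistry | None = None,
    ci_max_outcomes: int = CI_MAX_OUTCOMES,
    link: str = "logistic",
):
    """Full cohort -> features -> score -> metrics pipeline for one cell.

    Returns an :class:`EvaluationResult`, or :class:`NotEvaluable` when the
    database cannot record the outcome (no inpatient/ER stroke events at all).
    A single-class cohort raises :class:`SingleClassError`.
    """
    registry = registry or builtin_concept_sets()
    pop_key = population + ("_sensitivity" if sensitivity else "")
    if not outcome_recordable(db, registry):
        return NotEvaluable(definition.name, db.name, pop_key, "outcome not recordable")
    labeled = labeled_cohort(db, pop_key, registry)
    feats = extract_features(db, labeled, registry)
    values = compute_scores(definition, feats).to_numpy()
    return evaluate_scores(
        definition.name,
        db.name,
        pop_key,
        values,
        labeled["label"].to_numpy(),
        ci_max_outcomes=ci_max_outcomes,
        link=link,
    )
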