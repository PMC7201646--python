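"""Synthetic multi-database generator with a known stroke-risk mechanism.

Each :class:`DatabaseProfile` emulates one flavour of observational database
seen in multi-site validation networks: employer claims truncated at 65,
Medicare-supplemental data starting at 65, mixed-age Medicaid and EHR sources,
a small hospital database with fewer than 100 outcomes, and a primary-care
database that records no inpatient stroke at all.

Mechanism, per person:

1. demographics (sex, age at index) and a single observation period with a
   configurable fraction of persons given >= 730 days of pre-index history;
2. a qualifying atrial-fibrillation presentation satisfying exactly one of the
   three index rules (two records on distinct dates / one inpatient record /
   one record with an ECG within 30 days prior), with a configurable mix;
3. pre-index condition history drawn from age-dependent prevalences;
4. latent 1-year stroke risk ``expit(b0 + beta . true_features)`` with the
   intercept solved numerically so the *eligible-cohort* expected outcome rate
   equals ``target_outcome_rate``;
5. a counterfactual stroke day uniform on 1..365 for cases;
6. treatment by indication: anticoagulant prescription probability increasing
   in latent risk; with probability ``efficacy`` an anticoagulant dated before
   the counterfactual stroke day deletes the stroke event;
7. stroke events emitted with inpatient/ER context only when the profile says
   the database can record them (otherwise outpatient context).

Everything is driven by a single integer seed through named substreams so that
adding draws to one stage does not perturb the others.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .core import LongitudinalDatabase
from .concepts import ConceptSetRegistry, builtin_concept_sets

_EPOCH = np.datetime64("2012-01-01")
_INDEX_SPAN_DAYS = 365 * 5  # index dates drawn from 2012-2016

_STREAMS = {"persons": 1, "history": 2, "outcomes": 3, "treatment": 4}

INDEX_RULES = ("two_records", "inpatient", "ecg_prior")


class GeneratorError(RuntimeError):
    pass


@dataclasses.dataclass(frozen=True)
class TreatmentPolicy:
    """How anticoagulant prescribing follows latent risk, and how well it works."""

    treated_fraction: float = 0.35  # marginal fraction prescribed during time-at-risk
    assignment_slope: float = 1.0   # log-odds of treatment per unit latent log-odds of stroke
    efficacy: float = 0.5           # P(an anticoagulant before the stroke day prevents it)


#: (prevalence at age 70, change per decade of age); clipped to [0.005, 0.98].
DEFAULT_PREVALENCE: dict[str, tuple[float, float]] = {
    "hypertension": (0.55, 0.08),
    "diabetes": (0.22, 0.02),
    "congestive_heart_failure": (0.18, 0.05),
    "vascular_disease": (0.15, 0.05),
    "proteinuria": (0.08, 0.02),
    "esrd_or_low_egfr": (0.07, 0.03),
    "liver_disease": (0.04, 0.0),
    "coronary_heart_disease": (0.20, 0.05),
    "rheumatoid_arthritis": (0.04, 0.0),
    "chronic_renal_disease": (0.12, 0.05),
    "valvular_heart_disease": (0.10, 0.04),
    "smoking": (0.12, -0.02),
    "family_history_chf": (0.05, 0.0),
    "prior_stroke": (0.06, 0.02),
    "prior_anticoagulant": (0.10, 0.02),
}

#: Log-odds contribution of each true risk factor; "age_per_year" is centred at 70.
DEFAULT_BETAS: dict[str, float] = {
    "age_per_year": 0.05,
    "hypertension": 0.25,
    "diabetes": 0.30,
    "congestive_heart_failure": 0.35,
    "vascular_disease": 0.30,
    "proteinuria": 0.15,
    "esrd_or_low_egfr": 0.30,
    "coronary_heart_disease": 0.20,
    "chronic_renal_disease": 0.25,
    "valvular_heart_disease": 0.20,
    "smoking": 0.25,
}


@dataclasses.dataclass(frozen=True)
class DatabaseProfile:
    name: str
    n_persons: int
    age_range: tuple[int, int]
    female_fraction: float = 0.55
    target_outcome_rate: float = 0.03
    inpatient_stroke_available: bool = True
    prevalence_map: Mapping[str, tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    true_betas: Mapping[str, float] = dataclasses.field(default_factory=lambda: dict(DEFAULT_BETAS))
    treatment_policy: TreatmentPolicy = TreatmentPolicy()
    washout_fraction: float = 0.85
    index_rule_mix: tuple[float, float, float] = (0.45, 0.35, 0.20)  # two_records, inpatient, ecg

    def __post_init__(self) -> None:
        if self.n_persons < 1:
            raise ValueError("n_persons must be >= 1")
        if self.age_range[0] > self.age_range[1]:
            raise ValueError("age_range min must be <= max")
        for label, p in (
            ("female_fraction", self.female_fraction),
            ("target_outcome_rate", self.target_outcome_rate),
            ("washout_fraction", self.washout_fraction),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} must be a proportion in [0,1], got {p}")
        if abs(sum(self.index_rule_mix) - 1.0) > 1e-9:
            raise ValueError("index_rule_mix must sum to 1")


_PRESETS: dict[str, dict] = {
    # Employer-sponsored claims: members aged <= 65, low stroke rate.
    "claims_under65": dict(n_persons=20_000, age_range=(18, 65), target_outcome_rate=0.013),
    # Medicare-supplemental claims: members aged >= 65, high stroke rate.
    "medicare_65plus": dict(n_persons=20_000, age_range=(65, 95), target_outcome_rate=0.044),
    # Medicaid: mixed ages, highest stroke rate.
    "medicaid_mixed": dict(n_persons=15_000, age_range=(18, 90), target_outcome_rate=0.046),
    # Large EHR source: mixed ages, low stroke rate.
    "ehr_large": dict(n_persons=30_000, age_range=(18, 90), target_outcome_rate=0.012),
    # Small tertiary-hospital EHR: expected eligible-cohort outcomes < 100.
    "hospital_small": dict(n_persons=2_000, age_range=(18, 90), target_outcome_rate=0.020),
    # Primary-care database with no inpatient/ER stroke recording.
    "no_inpatient_stroke": dict(
        n_persons=8_000,
        age_range=(18, 90),
        target_outcome_rate=0.020,
        inpatient_stroke_available=False,
        index_rule_mix=(0.70, 0.0, 0.30),  # no inpatient records at all
    ),
}


def preset_names() -> list[str]:
    return sorted(_PRESETS)


def make_profile(preset_name: str, **overrides) -> DatabaseProfile:
    """Build one of the named database profiles, optionally overriding fields."""
    if preset_name not in _PRESETS:
        raise ValueError(
            f"unknown preset {preset_name!r}; available: {', '.join(preset_names())}"
        )
    kwargs = dict(_PRESETS[preset_name])
    kwargs.update(overrides)
    return DatabaseProfile(name=kwargs.pop("name", preset_name), **kwargs)


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[stream])))


def _pick_codes(rng: np.random.Generator, registry: ConceptSetRegistry, set_name: str, n: int):
    codes = sorted(registry.codes(set_name))
    return np.asarray(codes, dtype=object)[rng.integers(0, len(codes), n)]


def generate_database(
    profile: DatabaseProfile, seed: int
) -> tuple[LongitudinalDatabase, pd.DataFrame]:
    """Generate one database plus its per-person ground truth.

    Deterministic given ``(profile, seed)``. The ground-truth frame carries the
    latent risk, the counterfactual stroke day, treatment assignment, whether
    the stroke was prevented, the emitted stroke day, an ``eligible`` flag
    (female, >=730 days washout, no prior stroke, no prior anticoagulant — the
    all-ages target-population criteria), and the true risk-factor flags.
    """
    registry = builtin_concept_sets()
    n = profile.n_persons
    rng_p = _rng(seed, "persons")
    rng_h = _rng(seed, "history")
    rng_o = _rng(seed, "outcomes")
    rng_t = _rng(seed, "treatment")

    female = rng_p.random(n) < profile.female_fraction
    lo, hi = profile.age_range
    age = rng_p.integers(lo, hi + 1, n)
    index_day = rng_p.integers(0, _INDEX_SPAN_DAYS, n)
    washout_ok = rng_p.random(n) < profile.washout_fraction
    pre_days = np.where(
        washout_ok, rng_p.integers(730, 2501, n), rng_p.integers(90, 730, n)
    )
    post_days = rng_p.integers(366, 1401, n)  # full time-at-risk always observed
    rule = rng_p.choice(3, size=n, p=list(profile.index_rule_mix))

    # --- event assembly buffers -------------------------------------------
    ev_pidx: list[np.ndarray] = []
    ev_day: list[np.ndarray] = []
    ev_code: list[np.ndarray] = []
    ev_domain: list[np.ndarray] = []
    ev_context: list[np.ndarray] = []

    def emit(pidx, day, codes, domain, context) -> None:
        pidx = np.asarray(pidx)
        if len(pidx) == 0:
            return
        ev_pidx.append(pidx)
        ev_day.append(np.asarray(day))
        ev_code.append(np.asarray(codes, dtype=object))
        ev_domain.append(np.full(len(pidx), domain, dtype=object))
        context = np.asarray(context, dtype=object)
        if context.ndim == 0:
            context = np.full(len(pidx), context, dtype=object)
        ev_context.append(context)

    all_idx = np.arange(n)

    # Qualifying atrial-fibrillation presentation.
    af_context = np.where(rule == 1, "inpatient", "outpatient").astype(object)
    emit(all_idx, index_day, _pick_codes(rng_h, registry, "atrial_fibrillation", n), "condition", af_context)
    two = all_idx[rule == 0]
    emit(
        two,
        index_day[two] + rng_h.integers(1, 151, len(two)),
        _pick_codes(rng_h, registry, "atrial_fibrillation", len(two)),
        "condition",
        "outpatient",
    )
    ecg = all_idx[rule == 2]
    emit(
        ecg,
        index_day[ecg] - rng_h.integers(0, 31, len(ecg)),
        _pick_codes(rng_h, registry, "ecg", len(ecg)),
        "procedure",
        "outpatient",
    )

    # Pre-index condition / drug history.
    def history_day(pidx) -> np.ndarray:
        back = 1 + np.floor(rng_h.random(len(pidx)) * (pre_days[pidx] - 1)).astype(int)
        return index_day[pidx] - back

    flags: dict[str, np.ndarray] = {}
    for cond, (base, slope) in profile.prevalence_map.items():
        p = np.clip(base + slope * (age - 70) / 10.0, 0.005, 0.98)
        has = rng_h.random(n) < p
        flags[cond] = has
        pidx = all_idx[has]
        if cond == "prior_stroke":
            set_name, domain = "stroke", "condition"
            if profile.inpatient_stroke_available:
                ctx = np.where(rng_h.random(len(pidx)) < 0.5, "inpatient", "outpatient").astype(object)
            else:
                ctx = np.full(len(pidx), "outpatient", dtype=object)
        elif cond == "prior_anticoagulant":
            set_name, domain, ctx = "anticoagulant", "drug", "outpatient"
        else:
            set_name = cond
            domain = registry.get(cond).domain
            ctx = "outpatient"
        emit(pidx, history_day(pidx), _pick_codes(rng_h, registry, set_name, len(pidx)), domain, ctx)

    # Latent risk, calibrated on the eligible (all-ages female) cohort.
    betas = dict(profile.true_betas)
    lin = betas.get("age_per_year", 0.0) * (age - 70.0)
    for cond, flag in flags.items():
        lin = lin + betas.get(cond, 0.0) * flag
    eligible = (
        female & washout_ok & ~flags.get("prior_stroke", np.zeros(n, bool))
        & ~flags.get("prior_anticoagulant", np.zeros(n, bool))
    )
    if not eligible.any():
        raise GeneratorError("no eligible persons; increase n_persons or washout_fraction")
    target = profile.target_outcome_rate
    lin_elig = lin[eligible]

    def gap(b0: float) -> float:
        return float(expit(b0 + lin_elig).mean() - target)

    try:
        b0 = brentq(gap, -30.0, 10.0)
    except ValueError as exc:
        raise GeneratorError(
            "intercept solver could not bracket the target outcome rate; "
            "adjust prevalence_map or true_betas"
        ) from exc
    risk = expit(b0 + lin)

    case = rng_o.random(n) < risk
    stroke_day = rng_o.integers(1, 366, n)

    pol = profile.treatment_policy
    if pol.treated_fraction <= 0.0:
        treated = np.zeros(n, bool)
    else:
        t_lin = logit(min(max(pol.treated_fraction, 1e-9), 1 - 1e-9))
        t_prob = expit(t_lin + pol.assignment_slope * (lin - lin_elig.mean()))
        treated = rng_t.random(n) < t_prob
    ac_day = rng_t.integers(1, 366, n)
    prevented = case & treated & (ac_day < stroke_day) & (rng_t.random(n) < pol.efficacy)
    emitted_case = case & ~prevented

    sidx = all_idx[emitted_case]
    if profile.inpatient_stroke_available:
        s_ctx = np.where(rng_o.random(len(sidx)) < 0.7, "inpatient", "er").astype(object)
    else:
        s_ctx = np.full(len(sidx), "outpatient", dtype=object)
    emit(
        sidx,
        index_day[sidx] + stroke_day[sidx],
        _pick_codes(rng_o, registry, "stroke", len(sidx)),
        "condition",
        s_ctx,
    )
    tidx = all_idx[treated]
    emit(
        tidx,
        index_day[tidx] + ac_day[tidx],
        _pick_codes(rng_t, registry, "anticoagulant", len(tidx)),
        "drug",
        "outpatient",
    )

    # --- assemble tables ---------------------------------------------------
    person_ids = np.array([f"P{i:06d}" for i in range(n)], dtype=object)
    index_dates = _EPOCH + index_day.astype("timedelta64[D]")
    index_years = index_dates.astype("datetime64[Y]").astype(int) + 1970

    persons = pd.DataFrame(
        {
            "person_id": person_ids,
            "sex": np.where(female, "female", "male"),
            "year_of_birth": index_years - age,
        }
    )
    periods = pd.DataFrame(
        {
            "person_id": person_ids,
            "start_date": pd.to_datetime(_EPOCH + (index_day - pre_days).astype("timedelta64[D]")),
            "end_date": pd.to_datetime(_EPOCH + (index_day + post_days).astype("timedelta64[D]")),
        }
    )
    events = pd.DataFrame(
        {
            "person_id": person_ids[np.concatenate(ev_pidx)],
            "date": pd.to_datetime(_EPOCH + np.concatenate(ev_day).astype("timedelta64[D]")),
            "code": np.concatenate(ev_code),
            "domain": np.concatenate(ev_domain),
            "visit_context": np.concatenate(ev_context),
        }
    )
    events = events.sort_values(
        ["person_id", "date", "code", "visit_context"], kind="stable"
    ).reset_index(drop=True)

    truth = pd.DataFrame(
        {
            "person_id": person_ids,
            "female": female.astype(int),
            "age_at_index": age,
            "index_date": pd.to_datetime(index_dates),
            "eligible": eligible.astype(int),
            "latent_risk": risk,
            "counterfactual_stroke_day": np.where(case, stroke_day, np.nan),
            "treated": treated.astype(int),
            "anticoagulant_day": np.where(treated, ac_day, np.nan),
            "stroke_prevented": prevented.astype(int),
            "emitted_stroke_day": np.where(emitted_case, stroke_day, np.nan),
        }
    )
    for cond, flag in flags.items():
        truth[f"true_{cond}"] = flag.astype(int)

    db = LongitudinalDatabase(profile.name, persons, periods, events)
    return db, truth
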