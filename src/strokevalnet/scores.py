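"""Declarative implementations of the five stroke-risk models.

Each model is a :class:`ScoreDefinition`: an additive table of covariate
weights plus exhaustive closed age bands, loaded from the versioned fixture
``data/scores.yaml``. CHADS2, CHA2DS2-VASc, ATRIA and Framingham are integer
point scores; Q-Stroke is a reduced linear predictor. ATRIA and Framingham are
the no-prior-stroke variants, and Q-Stroke is the female model with its
UK-specific and measurement terms removed; all raw scores (not published risk
mappings) feed evaluation, since discrimination and logistic recalibration are
invariant to monotone transforms.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd
import yaml

MODEL_NAMES = ("ATRIA", "CHADS2", "CHA2DS2VASc", "Framingham", "QStroke")

_RANGE_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class AgeBand:
    min_age: int
    max_age: int
    weight: float


@dataclasses.dataclass(frozen=True)
class ScoreDefinition:
    name: str
    covariates: tuple[tuple[str, float], ...]
    age_bands: tuple[AgeBand, ...]
    output_kind: str  # "integer_points" | "linear_predictor"
    valid_range: tuple[float, float]
    excluded_predictors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        spans = sorted((b.min_age, b.max_age) for b in self.age_bands)
        for (lo1, hi1), (lo2, _) in zip(spans, spans[1:]):
            if lo2 <= hi1:
                raise ValueError(f"{self.name}: overlapping age bands")
        if spans[0][0] > 0 or any(b + 1 != c for (_, b), (c, _) in zip(spans, spans[1:])):
            raise ValueError(f"{self.name}: age bands must exhaustively cover all ages")

    def age_weight(self, age_years: int) -> float:
        for band in self.age_bands:
            if band.min_age <= age_years <= band.max_age:
                return band.weight
        raise ValueError(f"{self.name}: age {age_years} outside all bands")


@dataclasses.dataclass(frozen=True)
class ScoreResult:
    person_id: str
    model_name: str
    raw_score: float
    in_range: bool


def _parse_definition(name: str, spec: dict) -> ScoreDefinition:
    return ScoreDefinition(
        name=name,
        covariates=tuple((k, float(v)) for k, v in spec["points"].items()),
        age_bands=tuple(
            AgeBand(int(b["min"]), int(b["max"]), float(b["weight"])) for b in spec["age_bands"]
        ),
        output_kind=spec["output_kind"],
        valid_range=(float(spec["valid_range"][0]), float(spec["valid_range"][1])),
        excluded_predictors=tuple(spec.get("excluded_predictors", [])),
    )


def load_score_definitions(path: Union[str, Path]) -> dict[str, ScoreDefinition]:
    spec = yaml.safe_load(Path(path).read_text())
    return {name: _parse_definition(name, body) for name, body in spec.items()}


def builtin_score_definitions() -> dict[str, ScoreDefinition]:
    """The five shipped model definitions, keyed by model name."""
    text = resources.files("strokevalnet.data").joinpath("scores.yaml").read_text()
    spec = yaml.safe_load(text)
    defs = {name: _parse_definition(name, body) for name, body in spec.items()}
    assert tuple(sorted(defs)) == tuple(sorted(MODEL_NAMES))
    return defs


def compute_score(definition: ScoreDefinition, features: Mapping) -> ScoreResult:
    """Score one feature vector (any mapping with the covariates + ``age_years``)."""
    raw = definition.age_weight(int(features["age_years"]))
    for covariate, weight in definition.covariates:
        raw += weight * float(features[covariate])
    if definition.output_kind == "integer_points":
        raw = int(round(raw))
    lo, hi = definition.valid_range
    return ScoreResult(
        person_id=str(features.get("person_id", "")),
        model_name=definition.name,
        raw_score=raw,
        in_range=bool(lo - _RANGE_TOL <= raw <= hi + _RANGE_TOL),
    )


def compute_scores(definition: ScoreDefinition, features: pd.DataFrame) -> pd.Series:
    """Vectorised scoring of a features frame; returns a per-row score Series."""
    bands = sorted(definition.age_bands, key=lambda b: b.min_age)
    edges = [b.min_age for b in bands] + [bands[-1].max_age + 1]
    weights = np.asarray([b.weight for b in bands])
    idx = np.searchsorted(edges, features["age_years"].to_numpy(), side="right") - 1
    if (idx < 0).any() or (idx >= len(bands)).any():
        raise ValueError(f"{definition.name}: age outside all bands")
    raw = weights[idx].astype(float)
    for covariate, weight in definition.covariates:
        raw = raw + weight * features[covariate].to_numpy(dtype=float)
    if definition.output_kind == "integer_points":
        raw = np.rint(raw)
    lo, hi = definition.valid_range
    if ((raw < lo - _RANGE_TOL) | (raw > hi + _RANGE_TOL)).any():
        raise ValueError(f"{definition.name}: score outside valid_range")
    return pd.Series(raw, index=features.index, name=definition.name)
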