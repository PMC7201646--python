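"""Concept sets: named code lists that phenotype conditions, drugs and procedures.

The vocabulary shipped here is synthetic: codes are opaque strings namespaced
by concept-set name (``hypertension:002``). Real SNOMED/RxNorm lists belong to
the data owner; the pipeline only needs the *structure* — a name, a domain and
a stable, non-empty code set — which is what these provide.

``prior_stroke_tia`` shares the ``stroke`` codes: the synthetic vocabulary does
not represent TIA separately, and the cohort's prior-stroke exclusion uses this
set, which makes the prior-stroke predictor flag identically zero in-cohort.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterator, Union


class UnknownConceptSetError(KeyError):
    """Lookup of a concept-set name that is not in the registry."""


@dataclasses.dataclass(frozen=True)
class ConceptSet:
    name: str
    domain: str
    codes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.codes:
            raise ValueError(f"concept set {self.name!r} has no codes")


class ConceptSetRegistry:
    """Name-keyed collection of :class:`ConceptSet` with helpful lookup errors."""

    def __init__(self, sets: list[ConceptSet] | None = None):
        self._sets: dict[str, ConceptSet] = {}
        for cs in sets or []:
            self.add(cs)

    def add(self, cs: ConceptSet) -> None:
        if cs.name in self._sets:
            raise ValueError(f"duplicate concept set name {cs.name!r}")
        self._sets[cs.name] = cs

    def get(self, name: str) -> ConceptSet:
        try:
            return self._sets[name]
        except KeyError:
            raise UnknownConceptSetError(
                f"unknown concept set {name!r}; available: {', '.join(sorted(self._sets))}"
            ) from None

    def codes(self, name: str) -> frozenset[str]:
        return self.get(name).codes

    def names(self) -> list[str]:
        return sorted(self._sets)

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __iter__(self) -> Iterator[ConceptSet]:
        return iter(self._sets.values())

    def __len__(self) -> int:
        return len(self._sets)


#: Condition-type predictor rows of the five scores' covariate table.
CONDITION_PREDICTOR_SETS = (
    "diabetes",
    "congestive_heart_failure",
    "hypertension",
    "proteinuria",
    "esrd_or_low_egfr",
    "vascular_disease",
    "liver_disease",
    "smoking",
    "coronary_heart_disease",
    "rheumatoid_arthritis",
    "chronic_renal_disease",
    "valvular_heart_disease",
    "family_history_chf",
    "prior_stroke_tia",
)

_DOMAIN_OVERRIDES = {
    "ecg": "procedure",
    "anticoagulant": "drug",
    "smoking": "observation",
    "family_history_chf": "observation",
}

_CODES_PER_SET = 4


def _codes(namespace: str) -> frozenset[str]:
    return frozenset(f"{namespace}:{i:03d}" for i in range(_CODES_PER_SET))


def builtin_concept_sets() -> ConceptSetRegistry:
    """The deterministic built-in registry; identical code sets on every call."""
    registry = ConceptSetRegistry()
    core = ("atrial_fibrillation", "ecg", "stroke", "anticoagulant")
    for name in core + CONDITION_PREDICTOR_SETS:
        if name == "prior_stroke_tia":
            codes = _codes("stroke")  # alias: see module docstring
        else:
            codes = _codes(name)
        registry.add(ConceptSet(name, _DOMAIN_OVERRIDES.get(name, "condition"), codes))
    return registry


def save_concept_sets(registry: ConceptSetRegistry, path: Union[str, Path]) -> None:
    payload = [
        {"name": cs.name, "domain": cs.domain, "codes": sorted(cs.codes)}
        for cs in sorted(registry, key=lambda c: c.name)
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def load_concept_sets(path: Union[str, Path]) -> ConceptSetRegistry:
    payload = json.loads(Path(path).read_text())
    return ConceptSetRegistry(
        [ConceptSet(d["name"], d["domain"], frozenset(d["codes"])) for d in payload]
    )
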