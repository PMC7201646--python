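"""Multi-database network study: per-cell evaluation, aggregation, reports.

Runs every (database, population, model) cell independently, marks databases
that cannot record the outcome as not evaluable (the primary-care case with no
inpatient stroke records), reports small databases per-cell but excludes any
database with fewer than 100 outcomes from the mean/range aggregates, and
renders byte-stable outcome-rate and discrimination tables plus a markdown
summary.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .concepts import builtin_concept_sets
from .core import LongitudinalDatabase, load_database
from .evaluation import (
    CI_MAX_OUTCOMES,
    EvaluationResult,
    NotEvaluable,
    POPULATIONS,
    SingleClassError,
    evaluate_scores,
    labeled_cohort,
    outcome_recordable,
)
from .features import extract_features
from .scores import MODEL_NAMES, builtin_score_definitions
from .synth import generate_database, make_profile

AGGREGATE_MIN_OUTCOMES = 100

_DASH = "–"  # en dash used in printed ranges and intervals


@dataclasses.dataclass(frozen=True)
class DatabaseSource:
    """One study database: either a CSV directory or a synthetic preset."""

    name: str
    path: str | None = None
    preset: str | None = None
    seed: int | None = None
    n_persons: int | None = None

    def realize(self) -> tuple[LongitudinalDatabase, bool | None]:
        """Load or generate; second element is the profile's recordability flag."""
        if self.path is not None:
            return load_database(self.path, name=self.name), None
        if self.preset is None:
            raise ValueError(f"database {self.name!r} needs either path or preset")
        overrides = {"name": self.name}
        if self.n_persons is not None:
            overrides["n_persons"] = self.n_persons
        profile = make_profile(self.preset, **overrides)
        db, _ = generate_database(profile, seed=self.seed if self.seed is not None else 0)
        return db, profile.inpatient_stroke_available


@dataclasses.dataclass(frozen=True)
class StudyConfig:
    databases: tuple[DatabaseSource, ...]
    populations: tuple[str, ...] = POPULATIONS
    models: tuple[str, ...] = MODEL_NAMES
    aggregate_min_outcomes: int = AGGREGATE_MIN_OUTCOMES
    ci_max_outcomes: int = CI_MAX_OUTCOMES

    def __post_init__(self) -> None:
        if not (self.databases and self.populations and self.models):
            raise ValueError("databases, populations and models must be non-empty")
        if self.aggregate_min_outcomes <= 0 or self.ci_max_outcomes <= 0:
            raise ValueError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text())
        dbs = tuple(DatabaseSource(**d) for d in raw["databases"])
        kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in raw.items() if k != "databases"}
        return cls(databases=dbs, **kwargs)

    def to_yaml(self, path: Union[str, Path]) -> None:
        raw = {
            "databases": [
                {k: v for k, v in dataclasses.asdict(d).items() if v is not None}
                for d in self.databases
            ],
            "populations": list(self.populations),
            "models": list(self.models),
            "aggregate_min_outcomes": self.aggregate_min_outcomes,
            "ci_max_outcomes": self.ci_max_outcomes,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclasses.dataclass(frozen=True)
class Aggregate:
    mean_auroc: float
    min_auroc: float
    max_auroc: float
    n_databases: int


@dataclasses.dataclass
class NetworkSummary:
    config: StudyConfig
    cells: dict[tuple[str, str, str], EvaluationResult | NotEvaluable]
    aggregates: dict[tuple[str, str], Aggregate]
    rates: pd.DataFrame  # database, population, n, outcome_count, outcome_rate (or reason)


def _evaluate_database(
    db: LongitudinalDatabase, recordable_flag: bool | None, config: StudyConfig, registry
) -> tuple[dict, list[dict]]:
    """All cells for one database; cohorts/features computed once per population."""
    definitions = builtin_score_definitions()
    cells: dict = {}
    rate_rows: list[dict] = []

    recordable = recordable_flag if recordable_flag is not None else outcome_recordable(db, registry)
    if not recordable:
        for pop in config.populations:
            rate_rows.append(
                {"database": db.name, "population": pop, "n": None, "outcome_count": None,
                 "outcome_rate": None, "reason": "outcome not recordable"}
            )
            for model in config.models:
                cells[(db.name, pop, model)] = NotEvaluable(
                    model, db.name, pop, "outcome not recordable"
                )
        return cells, rate_rows

    for pop in config.populations:
        labeled = labeled_cohort(db, pop, registry)
        n = len(labeled)
        n_pos = int(labeled["label"].sum())
        rate_rows.append(
            {"database": db.name, "population": pop, "n": n, "outcome_count": n_pos,
             "outcome_rate": n_pos / n if n else float("nan"), "reason": None}
        )
        feats = extract_features(db, labeled, registry) if n else None
        labels = labeled["label"].to_numpy()
        for model in config.models:
            try:
                if n == 0:
                    raise SingleClassError("empty cohort")
                from .scores import compute_scores  # local import keeps module deps one-way

                values = compute_scores(definitions[model], feats).to_numpy()
                cells[(db.name, pop, model)] = evaluate_scores(
                    model, db.name, pop, values, labels,
                    ci_max_outcomes=config.ci_max_outcomes,
                )
            except SingleClassError as exc:
                cells[(db.name, pop, model)] = NotEvaluable(model, db.name, pop, str(exc))
    return cells, rate_rows


def aggregate_cells(
    cells: dict, config: StudyConfig
) -> dict[tuple[str, str], Aggregate]:
    """Unweighted mean and range over databases with enough outcomes."""
    out: dict[tuple[str, str], Aggregate] = {}
    for pop in config.populations:
        for model in config.models:
            values = [
                cell.auroc
                for (dbn, p, m), cell in cells.items()
                if p == pop
                and m == model
                and isinstance(cell, EvaluationResult)
                and cell.outcome_count >= config.aggregate_min_outcomes
            ]
            if values:
                out[(pop, model)] = Aggregate(
                    float(np.mean(values)), float(min(values)), float(max(values)), len(values)
                )
    return out


def run_network_study(config: StudyConfig) -> NetworkSummary:
    registry = builtin_concept_sets()
    cells: dict = {}
    rate_rows: list[dict] = []
    for source in config.databases:
        db, flag = source.realize()
        db_cells, db_rates = _evaluate_database(db, flag, config, registry)
        cells.update(db_cells)
        rate_rows.extend(db_rates)
    rates = pd.DataFrame(rate_rows)
    return NetworkSummary(config, cells, aggregate_cells(cells, config), rates)


# ---------------------------------------------------------------------------
# rendering


def _fmt_rate(row: pd.Series) -> str:
    if row["reason"]:
        return "–"
    return f"{100 * row['outcome_rate']:.2f} ({row['n']})"


def _fmt_cell(cell) -> str:
    if isinstance(cell, NotEvaluable):
        return "–"
    if cell.auroc_ci is None:
        return f"{cell.auroc:.2f}"
    lo, hi = cell.auroc_ci
    return f"{cell.auroc:.2f} ({lo:.2f}{_DASH}{hi:.2f})"


def render_report(summary: NetworkSummary, out_dir: Union[str, Path]) -> list[Path]:
    """Write outcome_rates.csv, discrimination.csv and summary.md (byte-stable)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = summary.config
    db_names = [d.name for d in config.databases]

    rates = summary.rates.set_index(["population", "database"])
    rate_rows = []
    for pop in config.populations:
        row = {"population": pop}
        for dbn in db_names:
            row[dbn] = _fmt_rate(rates.loc[(pop, dbn)])
        rate_rows.append(row)
    rates_path = out_dir / "outcome_rates.csv"
    pd.DataFrame(rate_rows).to_csv(rates_path, index=False, lineterminator="\n")

    disc_rows = []
    for pop in config.populations:
        for model in config.models:
            row = {"population": pop, "model": model}
            for dbn in db_names:
                row[dbn] = _fmt_cell(summary.cells[(dbn, pop, model)])
            disc_rows.append(row)
    disc_path = out_dir / "discrimination.csv"
    pd.DataFrame(disc_rows).to_csv(disc_path, index=False, lineterminator="\n")

    lines = ["# Network validation summary", ""]
    for pop in config.populations:
        lines.append(f"## {pop}")
        lines.append("")
        for model in config.models:
            agg = summary.aggregates.get((pop, model))
            if agg is None:
                lines.append(f"- {model}: no database met the aggregation threshold")
            else:
                lines.append(
                    f"- {model}: mean AUROC {agg.mean_auroc:.2f} "
                    f"(range {agg.min_auroc:.2f}{_DASH}{agg.max_auroc:.2f}) "
                    f"across {agg.n_databases} databases"
                )
        lines.append("")
    excluded = sorted(
        {
            dbn
            for (dbn, _, _), cell in summary.cells.items()
            if isinstance(cell, EvaluationResult)
            and cell.outcome_count < config.aggregate_min_outcomes
        }
    )
    not_eval = sorted(
        {dbn for (dbn, _, _), cell in summary.cells.items() if isinstance(cell, NotEvaluable)}
    )
    if excluded:
        lines.append(
            f"Databases with fewer than {config.aggregate_min_outcomes} outcomes are "
            f"reported per-cell but excluded from aggregates: {', '.join(excluded)}."
        )
    if not_eval:
        lines.append(f"Not evaluable (–): {', '.join(not_eval)}.")
    lines.append("")
    summary_path = out_dir / "summary.md"
    summary_path.write_text("\n".join(lines))

    return [rates_path, disc_path, summary_path]
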