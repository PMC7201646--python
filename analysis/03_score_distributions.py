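"""Replicate the five risk scores on every evaluable database (T2 population).

Writes results/score_summary.csv: per (database, model), the score mean, SD
and attained range on the all-ages female cohort. Age truncation moves the
whole distribution: the under-65 claims database sits at the bottom of every
age-weighted score, the 65+ database at the top.
"""

import pandas as pd

import strokevalnet as sv

from _databases import RESULTS, get_databases


def main() -> None:
    registry = sv.builtin_concept_sets()
    definitions = sv.builtin_score_definitions()
    rows = []
    for preset, (db, _) in get_databases().items():
        entries = sv.build_target_cohort(db, sv.T2, registry)
        feats = sv.extract_features(db, entries, registry)
        for name, definition in sorted(definitions.items()):
            scores = sv.compute_scores(definition, feats)
            rows.append(
                {
                    "database": preset,
                    "model": name,
                    "n": len(scores),
                    "mean": scores.mean(),
                    "sd": scores.std(),
                    "min": scores.min(),
                    "max": scores.max(),
                }
            )
    table = pd.DataFrame(rows).round(3)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "score_summary.csv", index=False, lineterminator="\n")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
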