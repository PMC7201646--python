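"""Simulate the six-database validation network and summarise its heterogeneity.

Writes results/simulated_databases.csv: per database, the person/event counts,
the eligible (all-ages female target population) size, and the realized
counterfactual vs emitted stroke rates — showing the treatment mechanism
suppressing a share of would-be strokes.
"""

import pandas as pd

from _databases import PRESETS, RESULTS, get_databases


def main() -> None:
    rows = []
    for preset, (db, truth) in get_databases().items():
        eligible = truth[truth["eligible"] == 1]
        rows.append(
            {
                "database": preset,
                "n_persons": len(db.persons),
                "n_events": len(db.events),
                "n_eligible": len(eligible),
                "counterfactual_stroke_rate": eligible["counterfactual_stroke_day"].notna().mean(),
                "emitted_stroke_rate": eligible["emitted_stroke_day"].notna().mean(),
                "treated_fraction": eligible["treated"].mean(),
            }
        )
    table = pd.DataFrame(rows).round(4)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "simulated_databases.csv", index=False, lineterminator="\n")
    print(table.to_string(index=False))
    print(
        "\nStroke rates span roughly "
        f"{100 * table['emitted_stroke_rate'].min():.1f}%-"
        f"{100 * table['emitted_stroke_rate'].max():.1f}% across databases; "
        "anticoagulant treatment suppresses part of the counterfactual rate everywhere."
    )


if __name__ == "__main__":
    main()
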