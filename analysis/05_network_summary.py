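"""Run the full network study and render the study-style report tables.

Writes results/network_report/: outcome_rates.csv (population x database rate
tables), discrimination.csv (AUROC with CIs shown only for cells under 1000
outcomes, dashes for the non-evaluable database), and summary.md with the
mean (range) AUROC per model aggregated over databases with >= 100 outcomes.
"""

import strokevalnet as sv

from _databases import BASE_SEED, PRESETS, RESULTS, get_databases, database_dir


def main() -> None:
    get_databases()  # ensure the cached CSVs exist
    config = sv.StudyConfig(
        databases=tuple(
            sv.DatabaseSource(p, path=str(database_dir(p))) for p in PRESETS
        )
    )
    summary = sv.run_network_study(config)
    out_dir = RESULTS / "network_report"
    paths = sv.render_report(summary, out_dir)
    for path in paths:
        print(f"wrote {path.relative_to(RESULTS.parent)}")
    print()
    print((out_dir / "summary.md").read_text())


if __name__ == "__main__":
    main()
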