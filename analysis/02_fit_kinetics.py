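#!/usr/bin/env python
"""Fit SFO/FOMC/HS kinetics to the simulated study and tabulate endpoints.

Reads results/curves_paper.csv (run 01_simulate_study.py first), fits all
three models per curve, selects the best by chi-square error, and writes
the summary table (CSV + Markdown) plus a per-soil report under results/.
"""

from pathlib import Path

from minkin import (
    fit_all,
    fit_report_rows,
    read_curves_csv,
    write_fit_table,
    write_markdown_report,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    curves = read_curves_csv(RESULTS / "curves_paper.csv")
    outcomes = fit_all(curves, seed=SEED)
    rows = fit_report_rows(outcomes)
    write_fit_table(rows, RESULTS / "fit_table.csv", format="csv")
    write_fit_table(rows, RESULTS / "fit_table.md", format="markdown")
    write_markdown_report(curves, outcomes, RESULTS / "report.md")

    n_good = sum(1 for o in outcomes if o.selected and not o.selected.poor_fit)
    by_model: dict[str, int] = {}
    for o in outcomes:
        if o.selected:
            name = o.selected.params.model_id.value
            by_model[name] = by_model.get(name, 0) + 1
    print(f"fitted {len(curves)} curves; {n_good} pass the chi2 < 15% rule")
    print(f"selected families: {by_model}")
    print(f"tables at {RESULTS / 'fit_table.csv'} and report at {RESULTS / 'report.md'}")


if __name__ == "__main__":
    main()
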