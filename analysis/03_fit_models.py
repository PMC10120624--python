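#!/usr/bin/env python
"""Fit the ANCOVA suite to the quantified cohort.

Paired (pair-blocked) and unpaired (covariate-adjusted) models for the
terminal-type mean CB1R measure and the single-plane sum CB1R measure, with
Bonferroni post hoc group contrasts, exposure-history ratio tests, and
demographic comparisons.  Writes the model tables and a text report to
results/.
"""

from pathlib import Path

import pandas as pd

from cb1rquant import measure, pipeline

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    layer_summaries = pd.read_csv(RESULTS / "layer_summaries.csv", comment="#")
    records = pd.read_csv(RESULTS / "bouton_records.csv", comment="#")
    manifest = pd.read_csv(SCRATCH / "cohort" / "manifest.csv")
    long_table = measure.layer_table_long(layer_summaries)
    _, median = measure.split_expressor_class(records)
    report, tables = pipeline._stats_stage(
        long_table, layer_summaries, manifest, median
    )
    tables.to_csv(RESULTS / "anova_tables.csv", index=False)
    (RESULTS / "stats_report.txt").write_text(report)
    print(report)
    print(f"tables -> {RESULTS / 'anova_tables.csv'}")


if __name__ == "__main__":
    main()
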