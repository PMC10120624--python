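#!/usr/bin/env python
"""Reference-cohort arithmetic: ratio table, percent differences, demographics.

Reproduces, from the printed per-pair inputs, the reciprocal ligand-binding
vs IHC ratio table with its magnitude differences and column statistics; the
terminal-type percent group differences implied by the published group means;
and the exact test on cannabis-use history counts.  Writes three CSVs under
results/.
"""

from pathlib import Path

import pandas as pd

from cb1rquant import cohortdata, stats

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    pr = cohortdata.PAIR_RATIOS
    out = stats.build_pair_ratio_table(pr["ihc_ratio_pct"], pr["ligand_ratio_pct"])
    out.table.to_csv(RESULTS / "pair_ratio_table.csv", index=False)
    out.summary.to_csv(RESULTS / "pair_ratio_summary.csv", index=False)
    print("pair-ratio column summary:")
    print(out.summary.round(2).to_string(index=False))

    rows = []
    for cls, means in cohortdata.GROUP_MEAN_CB1R_ADU.items():
        rows.append(
            {
                "terminal_class": cls,
                "ctrl_mean_adu": means["Ctrl"],
                "sz_mean_adu": means["SZ"],
                "percent_difference": stats.group_percent_difference(
                    means["SZ"], means["Ctrl"]
                ),
            }
        )
    pct = pd.DataFrame(rows)
    pct.to_csv(RESULTS / "group_percent_differences.csv", index=False)
    print("\ngroup percent differences (SZ vs Ctrl):")
    print(pct.round(2).to_string(index=False))

    (y_c, n_c), (y_s, n_s) = (
        cohortdata.CANNABIS_HISTORY_COUNTS["Ctrl"],
        cohortdata.CANNABIS_HISTORY_COUNTS["SZ"],
    )
    p = stats.fisher_exact_two_sided([[y_c, n_c - y_c], [y_s, n_s - y_s]])
    demo = pd.DataFrame(
        [{"variable": "cannabis_history", "test": "fisher_exact",
          "ctrl": f"{y_c}/{n_c}", "sz": f"{y_s}/{n_s}", "p": p}]
    )
    demo.to_csv(RESULTS / "demographics_tests.csv", index=False)
    print(f"\ncannabis history {y_c}/{n_c} vs {y_s}/{n_s}: exact p = {p:.4f}")


if __name__ == "__main__":
    main()
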