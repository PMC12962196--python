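#!/usr/bin/env python
"""Step 3 — group statistics.

From the fitted region table: per (ROI, metric), exact Wilcoxon rank-sum
comparisons of the lesion and contralateral sides against pre-lesion
values (n = 8 injured segments per group), percent changes, and the
8x8 metric correlation matrix over the pooled entries (7 ROIs x 2
segments x 4 subjects x 3 groups = 168 entries per metric).  Writes
stats_report.tsv, correlation_matrix.tsv and correlation_pvalues.tsv
under results/, and prints the headline percent changes.
"""

from pathlib import Path

import pandas as pd

from cordmap.roistats import compute_stats

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    region = pd.read_csv(ROOT / "region_table.tsv", sep="\t")
    report = compute_stats(region, lesion_side="left")
    report.write(ROOT)
    comp = report.comparisons
    print(f"correlation entries per metric: {report.n_entries}")
    print("\nlesion-side percent changes (significant rows):")
    sig = comp[comp.p_lesion_vs_pre < 0.05]
    cols = ["roi", "metric", "percent_change_lesion", "p_lesion_vs_pre",
            "stars_lesion"]
    print(sig[cols].to_string(index=False))


if __name__ == "__main__":
    main()
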