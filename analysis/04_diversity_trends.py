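#!/usr/bin/env python
"""Shannon-entropy diversity of every sample and its longitudinal trend.

Entropy is computed on UMI-weighted amino-acid clone frequencies; per
subset, entropy is regressed on months post-treatment (OLS slope, adjusted
R-squared, two-sided p).
"""

import sys
from pathlib import Path

import pandas as pd

from tcrtrack.core import read_clonotype_table
from tcrtrack.diversity import entropy_trend, sample_entropy

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_clonotype_table(OUT / "cohort.tsv", OUT / "subjects.tsv")
    rows = [
        dict(
            subject_id=s.subject_id, subset=s.subset,
            timepoint_months=s.timepoint_months,
            entropy=sample_entropy(s),
            entropy_normalized=sample_entropy(s, normalized=True),
        )
        for s in cohort.samples
        if s.records
    ]
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "diversity.tsv", sep="\t", index=False)

    trends = []
    for subset, grp in df.groupby("subset"):
        slope, r2, p = entropy_trend(list(zip(grp.timepoint_months, grp.entropy)))
        trends.append(dict(subset=subset, slope_per_month=slope, adjusted_r2=r2, p_value=p))
        direction = "declines" if slope < 0 else "increases"
        print(f"{subset}: entropy {direction} at {slope:+.4f}/month "
              f"(adj r2 = {r2:.2f}, p = {p:.3g})")
    pd.DataFrame(trends).to_csv(OUT / "diversity_trends.tsv", sep="\t", index=False)
    print(f"tables -> {OUT}/diversity.tsv, diversity_trends.tsv")


if __name__ == "__main__":
    main()
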