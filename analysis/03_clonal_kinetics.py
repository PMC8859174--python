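#!/usr/bin/env python
"""Track dominant memory clones longitudinally (persistence and turnover).

For each subject and memory subset: persistence of the baseline top-100
clones at every follow-up, and the split of follow-up repertoire mass into
persistent versus new clones.  Cohort means are compared with paired
Wilcoxon tests (Bonferroni-corrected across timepoints).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from tcrtrack.core import read_clonotype_table
from tcrtrack.stats import bonferroni, wilcoxon_paired
from tcrtrack.tracking import partition_new_persistent, persistence_fraction, top_n_clones

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_clonotype_table(OUT / "cohort.tsv", OUT / "subjects.tsv")
    rows = []
    for subset in ("CD4_RO", "CD8_RO", "CD4_RA", "CD8_RA"):
        for subj in cohort.subjects:
            base = cohort.get_sample(subj.subject_id, 0, subset)
            if base is None:
                continue
            dominant = top_n_clones(base, 100)
            for tp in (6, 12, 24, 36):
                s = cohort.get_sample(subj.subject_id, tp, subset)
                if s is None:
                    continue
                persistent_mass, new_mass = partition_new_persistent(base, s)
                rows.append(
                    dict(
                        subject_id=subj.subject_id, subset=subset, timepoint_months=tp,
                        top100_persistence=persistence_fraction(dominant, s),
                        persistent_mass=persistent_mass, new_mass=new_mass,
                    )
                )
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "clonal_tracking.tsv", sep="\t", index=False)

    print("mean top-100 persistence (%) by subset and month:")
    summary = (
        df.pivot_table(index="subset", columns="timepoint_months", values="top100_persistence")
        * 100
    ).round(1)
    print(summary.to_string())

    # paired tests: persistence at each later timepoint vs 6 months
    for subset in ("CD4_RO", "CD8_RO"):
        sub = df[df.subset == subset].pivot(
            index="subject_id", columns="timepoint_months", values="top100_persistence"
        )
        ps = []
        for tp in (12, 24, 36):
            res = wilcoxon_paired(sub[6], sub[tp])
            ps.append(res.p_value)
        adj = bonferroni(ps)
        for tp, p in zip((12, 24, 36), adj):
            print(f"{subset}: persistence 6mo vs {tp}mo, Bonferroni p = {p:.4g}")
    print(f"table -> {OUT}/clonal_tracking.tsv")


if __name__ == "__main__":
    main()
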