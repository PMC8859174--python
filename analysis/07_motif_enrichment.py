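#!/usr/bin/env python
"""CDR3 k-mer motif enrichment of 6-month repertoires vs pooled baseline.

For each subject's CD4 memory sample at 6 months, interior k-mers (k=3..7,
minimum CDR3 length 7) are Fisher-tested against the pooled baseline
clonotypes of all subjects; clusters passing p < 1e-3 are scored for biased
V usage and summarized as the fraction of reads/clonotypes they cover.
"""

import sys
from pathlib import Path

import pandas as pd

from tcrtrack.core import aggregate_to_aa, read_clonotype_table
from tcrtrack.motifs import (
    enriched_motif_summary,
    motif_fisher,
    reference_v_usage,
    v_bias_score,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_clonotype_table(OUT / "cohort.tsv", OUT / "subjects.tsv")
    reference = [
        key for s in cohort.samples_at(0, "CD4_RO") for key in aggregate_to_aa(s)
    ]
    v_usage = reference_v_usage(reference)

    cluster_rows, summary_rows = [], []
    for s in cohort.samples_at(6, "CD4_RO"):
        sample_keys = list(aggregate_to_aa(s))
        clusters = motif_fisher(sample_keys, reference, alpha_fisher=1e-3)
        for cl in clusters:
            v_bias_score(cl, v_usage)
            cluster_rows.append(
                dict(subject_id=s.subject_id, motif=cl.motif, k=len(cl.motif),
                     fisher_p=cl.fisher_p, v_bias_p=cl.v_bias_p,
                     v_biased=cl.v_biased, members=len(cl.member_keys))
            )
        reads_frac, clone_frac = enriched_motif_summary(clusters, s)
        summary_rows.append(
            dict(subject_id=s.subject_id, n_clusters=len(clusters),
                 enriched_read_pct=100 * reads_frac,
                 enriched_clonotype_pct=100 * clone_frac)
        )
    pd.DataFrame(cluster_rows).to_csv(OUT / "motif_clusters.tsv", sep="\t", index=False)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(OUT / "motif_summary.tsv", sep="\t", index=False)

    with_hits = summary[summary.n_clusters > 0]
    print(f"{len(with_hits)}/{len(summary)} subjects carry enriched motifs at 6 months")
    if not with_hits.empty:
        print(with_hits.to_string(index=False))
    print(f"tables -> {OUT}/motif_clusters.tsv, motif_summary.tsv")


if __name__ == "__main__":
    main()
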