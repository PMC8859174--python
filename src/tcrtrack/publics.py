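"""Public clonotypes: detection across individuals, sharing patterns,
convergent-recombination counts, and HLA stratification.

A clonotype (V gene, J gene, CDR3 amino acids) is *public* when it is
detected at sufficient size in at least two individuals.  The inclusion
rule defaults to the stricter per-individual reading — at least
``min_reads`` reads in each of at least ``min_subjects`` subjects — with a
pooled-total alternative available (``per_subject_threshold=False``).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

from .core import ClonotypeKey, CohortDataset, RepertoireSample, aggregate_to_aa, normalize_allele


def identify_public(
    cohort: CohortDataset,
    subset: str,
    timepoint: int | None,
    min_reads: int = 2,
    min_subjects: int = 2,
    per_subject_threshold: bool = True,
) -> dict[ClonotypeKey, frozenset[str]]:
    """Public clonotypes at one timepoint (or pooled over all timepoints).

    Returns key -> set of qualifying subjects.  With the default
    per-subject threshold, a subject qualifies only if it carries the key at
    >= ``min_reads`` reads; with the pooled alternative every carrier
    qualifies provided the cohort-wide read total reaches ``min_reads``.
    """
    if timepoint is None:
        samples = [s for s in cohort.samples if s.subset == subset]
    else:
        samples = cohort.samples_at(timepoint, subset)
    by_subject: dict[str, dict[ClonotypeKey, int]] = defaultdict(dict)
    for s in samples:
        agg = aggregate_to_aa(s)
        for k, prof in agg.items():
            by_subject[s.subject_id][k] = by_subject[s.subject_id].get(k, 0) + prof.total_reads
    if len(by_subject) < 2:
        raise ValueError("need samples from at least 2 subjects")

    carriers: dict[ClonotypeKey, set[str]] = defaultdict(set)
    totals: dict[ClonotypeKey, int] = defaultdict(int)
    for sid, clones in by_subject.items():
        for k, reads in clones.items():
            totals[k] += reads
            if per_subject_threshold:
                if reads >= min_reads:
                    carriers[k].add(sid)
            else:
                carriers[k].add(sid)

    out: dict[ClonotypeKey, frozenset[str]] = {}
    for k, subs in carriers.items():
        if not per_subject_threshold and totals[k] < min_reads:
            continue
        if len(subs) >= min_subjects:
            out[k] = frozenset(subs)
    return out


def sharing_distribution(
    public_map: Mapping[ClonotypeKey, frozenset[str]]
) -> dict[frozenset[str], int]:
    """Counts of public keys per exact subject combination (upset counts).

    The counts sum to the number of public keys.
    """
    out: dict[frozenset[str], int] = defaultdict(int)
    for subs in public_map.values():
        out[frozenset(subs)] += 1
    return dict(out)


def convergence_counts(
    sample: RepertoireSample, keys: Iterable[ClonotypeKey]
) -> dict[ClonotypeKey, int]:
    """Distinct nucleotide encodings per amino-acid key within one sample."""
    agg = aggregate_to_aa(sample)
    out: dict[ClonotypeKey, int] = {}
    for k in keys:
        prof = agg.get(k)
        if prof is None:
            warnings.warn(f"key {k} absent from sample; convergence reported as 0")
            out[k] = 0
        else:
            out[k] = len(prof.nt_variants)
    return out


def stratify_by_hla(
    cohort: CohortDataset, allele: str
) -> tuple[CohortDataset, CohortDataset]:
    """Partition a cohort into carriers and non-carriers of an HLA allele.

    Matching is by prefix at the resolution of the query (so "DRB1*15"
    matches "DRB1*15:01"); the two halves reconstitute the input.
    """
    a = normalize_allele(allele)

    def carries(subject) -> bool:
        return any(x == a or x.startswith(a + ":") for x in subject.hla_alleles)

    carrier_ids = {s.subject_id for s in cohort.subjects if carries(s)}
    pos = CohortDataset(
        samples=[s for s in cohort.samples if s.subject_id in carrier_ids],
        subjects=[s for s in cohort.subjects if s.subject_id in carrier_ids],
    )
    neg = CohortDataset(
        samples=[s for s in cohort.samples if s.subject_id not in carrier_ids],
        subjects=[s for s in cohort.subjects if s.subject_id not in carrier_ids],
    )
    return pos, neg
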