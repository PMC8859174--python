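"""Dominant-clone selection and longitudinal persistence statistics.

Tracking operates on amino-acid clonotypes (so it is invariant to silent
nucleotide substitutions) and ranks clones by UMI-corrected abundance when
UMIs are present, read count otherwise.
"""

from __future__ import annotations

import warnings
from typing import Sequence

from .core import ClonotypeKey, RepertoireSample, aggregate_to_aa


def _abundances(sample: RepertoireSample) -> dict[ClonotypeKey, int]:
    agg = aggregate_to_aa(sample)
    use_umis = any(p.total_umis > 0 for p in agg.values())
    return {k: (p.total_umis if use_umis else p.total_reads) for k, p in agg.items()}


def top_n_clones(sample: RepertoireSample, n: int = 100) -> list[ClonotypeKey]:
    """The n most abundant amino-acid clonotypes ("dominant" clones).

    Deterministic tie-break: abundance descending, then cdr3_aa, v_gene,
    j_gene lexicographic.  Returns the whole repertoire when it holds fewer
    than n clones.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    ab = _abundances(sample)
    ordered = sorted(ab.items(), key=lambda kv: (-kv[1], kv[0].cdr3_aa, kv[0].v_gene, kv[0].j_gene))
    return [k for k, _ in ordered[:n]]


def persistence_fraction(
    baseline_top: Sequence[ClonotypeKey],
    followup: RepertoireSample,
    min_reads: int = 1,
) -> float:
    """Fraction of baseline dominant clones still detected at follow-up.

    "Detected" means present with abundance >= ``min_reads`` (default 1, the
    loosest reading of detection).
    """
    if not baseline_top:
        raise ValueError("baseline clone list must be non-empty")
    ab = _abundances(followup)
    hit = sum(1 for k in baseline_top if ab.get(k, 0) >= min_reads)
    return hit / len(baseline_top)


def partition_new_persistent(
    baseline: RepertoireSample, followup: RepertoireSample
) -> tuple[float, float]:
    """Split follow-up repertoire mass into persistent vs new clones.

    Returns (persistent_fraction, new_fraction) of the follow-up abundance
    mass, by whether each amino-acid clonotype was detected at baseline at
    any abundance; the fractions sum to 1.
    """
    if not baseline.records:
        raise ValueError("empty baseline sample")
    if not followup.records:
        raise ValueError("empty follow-up sample")
    base_keys = set(aggregate_to_aa(baseline))
    ab = _abundances(followup)
    total = sum(ab.values())
    persistent = sum(v for k, v in ab.items() if k in base_keys)
    return persistent / total, 1.0 - persistent / total


def repertoire_overlap(
    a: RepertoireSample, b: RepertoireSample
) -> tuple[int, float]:
    """Shared amino-acid clone count and Jaccard index of two samples."""
    ka, kb = set(aggregate_to_aa(a)), set(aggregate_to_aa(b))
    union = ka | kb
    if not union:
        warnings.warn("overlap of two empty repertoires; jaccard reported as 0")
        return 0, 0.0
    shared = len(ka & kb)
    return shared, shared / len(union)
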