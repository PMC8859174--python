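"""CDR3 k-mer motif enrichment (GLIPH-style local similarity).

K-mers of length 3..7 are drawn from the CDR3 interior (3 residues trimmed
from the left, 2 from the right, minimum CDR3 length 7) and tested for
over-representation in a sample versus a reference repertoire with a
one-sided Fisher exact test on the clonotype-level 2x2 table; clusters
passing the Fisher threshold (default p < 1e-3) are scored for biased
V-gene usage with a Bonferroni-corrected binomial tail (flagged at
p < 0.05).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .core import ClonotypeKey, RepertoireSample, aggregate_to_aa

DEFAULT_K_RANGE = (3, 7)
TRIM_LEFT = 3
TRIM_RIGHT = 2
MIN_CDR3_LEN = 7


def extract_kmers(
    cdr3_aa: str,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    trim_left: int = TRIM_LEFT,
    trim_right: int = TRIM_RIGHT,
    min_cdr3_len: int = MIN_CDR3_LEN,
) -> set[str]:
    """Distinct interior k-mers of one CDR3 (empty for short CDR3s)."""
    if len(cdr3_aa) < min_cdr3_len:
        return set()
    interior = cdr3_aa[trim_left : len(cdr3_aa) - trim_right]
    out: set[str] = set()
    for k in range(k_range[0], k_range[1] + 1):
        for i in range(len(interior) - k + 1):
            out.add(interior[i : i + k])
    return out


@dataclass
class MotifCluster:
    """An enriched k-mer with its member clonotypes and test statistics."""

    motif: str
    member_keys: frozenset[ClonotypeKey]
    fisher_p: float
    sample_count: int
    reference_count: int
    sample_total: int
    reference_total: int
    v_bias_p: float = 1.0
    v_biased: bool = False
    top_v: str = ""


def motif_fisher(
    sample_keys: Sequence[ClonotypeKey],
    reference_keys: Sequence[ClonotypeKey],
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    alpha_fisher: float = 1e-3,
    trim_left: int = TRIM_LEFT,
    trim_right: int = TRIM_RIGHT,
    min_cdr3_len: int = MIN_CDR3_LEN,
) -> list[MotifCluster]:
    """Enriched motifs in a sample versus a reference repertoire.

    For every k-mer present in the sample, a one-sided Fisher exact test on
    (clonotypes containing the motif vs not) x (sample vs reference);
    clusters with p < ``alpha_fisher`` are kept, sorted by p then motif.
    """
    if not sample_keys:
        raise ValueError("empty sample")
    if not reference_keys:
        raise ValueError("empty reference")

    def kmer_sets(keys):
        return {
            key: extract_kmers(key.cdr3_aa, k_range, trim_left, trim_right, min_cdr3_len)
            for key in keys
        }

    sample_kmers = kmer_sets(set(sample_keys))
    ref_kmers = kmer_sets(set(reference_keys))
    n_s, n_r = len(sample_kmers), len(ref_kmers)

    members: dict[str, set[ClonotypeKey]] = defaultdict(set)
    for key, kmers in sample_kmers.items():
        for m in kmers:
            members[m].add(key)
    ref_counts: dict[str, int] = defaultdict(int)
    for key, kmers in ref_kmers.items():
        for m in kmers:
            if m in members:
                ref_counts[m] += 1

    # one-sided Fisher p is the hypergeometric upper tail of the 2x2 table;
    # evaluated vectorized across motifs
    motifs_list = sorted(members)
    a_arr = np.array([len(members[m]) for m in motifs_list])
    c_arr = np.array([ref_counts.get(m, 0) for m in motifs_list])
    p_arr = stats.hypergeom.sf(a_arr - 1, n_s + n_r, a_arr + c_arr, n_s)

    out: list[MotifCluster] = []
    for motif, a, c, p in zip(motifs_list, a_arr, c_arr, p_arr):
        keys = members[motif]
        a = int(a)
        c = int(c)
        if p < alpha_fisher:
            out.append(
                MotifCluster(
                    motif=motif,
                    member_keys=frozenset(keys),
                    fisher_p=float(p),
                    sample_count=a,
                    reference_count=c,
                    sample_total=n_s,
                    reference_total=n_r,
                )
            )
    out.sort(key=lambda cl: (cl.fisher_p, cl.motif))
    return out


def v_bias_score(
    cluster: MotifCluster, reference_v_usage: Mapping[str, float]
) -> float:
    """Bonferroni-corrected binomial tail p for the cluster's most
    over-represented V gene; 1.0 for single-member clusters."""
    n = len(cluster.member_keys)
    if n < 2:
        cluster.v_bias_p = 1.0
        cluster.v_biased = False
        return 1.0
    counts: dict[str, int] = defaultdict(int)
    for key in cluster.member_keys:
        counts[key.v_gene] += 1
    best_p, best_v = 1.0, ""
    for v, x in counts.items():
        pv = float(stats.binom.sf(x - 1, n, reference_v_usage.get(v, 0.0)))
        if pv < best_p:
            best_p, best_v = pv, v
    corrected = min(1.0, best_p * len(counts))
    cluster.v_bias_p = corrected
    cluster.v_biased = corrected < 0.05
    cluster.top_v = best_v
    return corrected


def reference_v_usage(keys: Iterable[ClonotypeKey]) -> dict[str, float]:
    counts: dict[str, int] = defaultdict(int)
    n = 0
    for k in keys:
        counts[k.v_gene] += 1
        n += 1
    return {v: c / n for v, c in counts.items()}


def enriched_motif_summary(
    clusters: Sequence[MotifCluster], sample: RepertoireSample
) -> tuple[float, float]:
    """Fractions of a sample's reads and clonotypes covered by enriched motifs.

    A clonotype belonging to several clusters is counted once.
    """
    agg = aggregate_to_aa(sample)
    if not agg:
        return 0.0, 0.0
    covered: set[ClonotypeKey] = set()
    for cl in clusters:
        covered |= cl.member_keys
    covered &= set(agg)
    use_umis = any(p.total_umis > 0 for p in agg.values())

    def w(prof):
        return prof.total_umis if use_umis else prof.total_reads

    total = sum(w(p) for p in agg.values())
    reads_frac = sum(w(agg[k]) for k in covered) / total if total else 0.0
    clone_frac = len(covered) / len(agg)
    return reads_frac, clone_frac
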