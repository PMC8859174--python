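"""K-mer motif enrichment: extraction, Fisher testing, V-bias, summaries."""

import math

import numpy as np
import pytest

from tcrtrack.core import ClonotypeKey, ClonotypeRecord, RepertoireSample
from tcrtrack.motifs import (
    MotifCluster,
    enriched_motif_summary,
    extract_kmers,
    motif_fisher,
    reference_v_usage,
    v_bias_score,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_key(rng, length=14, v_choices=("TRBV1", "TRBV2", "TRBV3")):
    aa = "C" + "".join(rng.choice(list(AA), size=length - 2)) + "F"
    return ClonotypeKey(str(rng.choice(v_choices)), "TRBJ1", aa)


class TestExtractKmers:
    def test_short_cdr3_empty(self):
        assert extract_kmers("CASSLG") == set()

    def test_interior_definition(self):
        kmers = extract_kmers("CASSQETQYF")
        # interior after trimming 3 left / 2 right is SQETQ
        assert kmers == {"SQE", "QET", "ETQ", "SQET", "QETQ", "SQETQ"}

    def test_interior_shorter_than_k(self):
        assert extract_kmers("CASSQETQYF", k_range=(6, 7)) == set()

    def test_each_kmer_once_per_clone(self):
        kmers = extract_kmers("CASAAAAAAAAF")  # repeated AAA appears once
        assert isinstance(kmers, set) and "AAA" in kmers


def fisher_tail_oracle(a, b, c, d):
    """One-sided (enrichment) Fisher p as an explicit hypergeometric tail sum."""
    M, K, n = a + b + c + d, a + c, a + b
    denom = math.comb(M, n)
    return sum(
        math.comb(K, k) * math.comb(M - K, n - k) for k in range(a, min(K, n) + 1)
    ) / denom


class TestFisher:
    def test_enriched_motif_detected(self):
        rng = np.random.default_rng(0)
        sample = [random_key(rng) for _ in range(70)]
        spiked = [
            ClonotypeKey("TRBV1", "TRBJ1", "CAS" + "QETQY" + k.cdr3_aa[8:])
            for k in [random_key(rng) for _ in range(30)]
        ]
        reference = [random_key(rng) for _ in range(1000)]
        clusters = motif_fisher(sample + spiked, reference)
        assert any(cl.motif == "QETQY" for cl in clusters)
        cl = next(cl for cl in clusters if cl.motif == "QETQY")
        assert cl.fisher_p == pytest.approx(
            fisher_tail_oracle(
                cl.sample_count,
                cl.sample_total - cl.sample_count,
                cl.reference_count,
                cl.reference_total - cl.reference_count,
            ),
            rel=1e-9,
        )

    def test_fisher_matches_oracle_on_random_tables(self):
        from scipy import stats as sps

        rng = np.random.default_rng(11)
        for _ in range(200):
            a = int(rng.integers(0, 30))
            b = int(rng.integers(1, 200))
            c = int(rng.integers(0, 50))
            d = int(rng.integers(1, 2000))
            p = float(sps.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))
            assert p == pytest.approx(fisher_tail_oracle(a, b, c, d), abs=1e-12)

    def test_equal_proportions_discarded(self):
        rng = np.random.default_rng(1)
        keys = [random_key(rng) for _ in range(100)]
        clusters = motif_fisher(keys, keys)
        assert clusters == []

    def test_sorted_by_p_then_motif(self):
        rng = np.random.default_rng(2)
        sample = [random_key(rng) for _ in range(50)]
        reference = [random_key(rng) for _ in range(500)]
        clusters = motif_fisher(sample, reference, alpha_fisher=0.5)
        ps = [(cl.fisher_p, cl.motif) for cl in clusters]
        assert ps == sorted(ps)

    def test_empty_reference_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            motif_fisher([random_key(rng)], [])


class TestVBias:
    def cluster_with(self, v_genes):
        rng = np.random.default_rng(7)
        keys = frozenset(
            ClonotypeKey(v, "TRBJ1", "C" + "".join(rng.choice(list(AA), 10)) + str(i) * 0 + "F")
            for i, v in enumerate(v_genes)
        )
        return MotifCluster("QET", keys, 1e-5, len(keys), 1, 100, 1000)

    def test_closed_form_extreme_bias(self):
        rng = np.random.default_rng(4)
        keys = frozenset(
            ClonotypeKey("TRBV9", "TRBJ1", "C" + "".join(rng.choice(list(AA), 9)) + "F")
            for _ in range(10)
        )
        cl = MotifCluster("QET", keys, 1e-5, 10, 1, 100, 1000)
        p = v_bias_score(cl, {"TRBV9": 0.05})
        assert p == pytest.approx(0.05**10, rel=1e-9)
        assert cl.v_biased

    def test_reference_usage_not_flagged(self):
        rng = np.random.default_rng(5)
        usage = {"TRBV1": 1 / 3, "TRBV2": 1 / 3, "TRBV3": 1 / 3}
        vs = [f"TRBV{1 + i % 3}" for i in range(9)]
        cl = self.cluster_with(vs)
        p = v_bias_score(cl, usage)
        assert not cl.v_biased and p > 0.05

    def test_single_member_undefined(self):
        cl = self.cluster_with(["TRBV1"])
        assert v_bias_score(cl, {"TRBV1": 0.01}) == 1.0

    def test_matches_binomial_tail_oracle(self):
        from scipy import stats as sps

        rng = np.random.default_rng(6)
        usage = {"TRBV1": 0.5, "TRBV2": 0.3, "TRBV3": 0.2}
        for _ in range(20):
            vs = rng.choice(["TRBV1", "TRBV2", "TRBV3"], size=int(rng.integers(2, 12)))
            cl = self.cluster_with(list(vs))
            got = v_bias_score(cl, usage)
            n = len(cl.member_keys)
            counts = {}
            for k in cl.member_keys:
                counts[k.v_gene] = counts.get(k.v_gene, 0) + 1
            best = min(
                sum(
                    math.comb(n, i) * usage[v] ** i * (1 - usage[v]) ** (n - i)
                    for i in range(x, n + 1)
                )
                for v, x in counts.items()
            )
            assert got == pytest.approx(min(1.0, best * len(counts)), rel=1e-9)


class TestSummary:
    def make_sample(self, aas):
        nts = {
            "CASSQETQYFFF": "TGTGCCAGCAGCCAGGAAACCCAGTACTTCTTCTTT",
            "CASSWWWWWWFF": "TGTGCCAGCAGCTGGTGGTGGTGGTGGTGGTTCTTT",
            "CASSQETQYAFF": "TGTGCCAGCAGCCAGGAAACCCAGTACGCCTTCTTT",
        }
        recs = [
            ClonotypeRecord(ClonotypeKey("TRBV1", "TRBJ1", aa), nts[aa], 10)
            for aa in aas
        ]
        return RepertoireSample("S", 0, "CD4_RO", recs)

    def test_no_clusters(self):
        s = self.make_sample(["CASSQETQYFFF"])
        assert enriched_motif_summary([], s) == (0.0, 0.0)

    def test_full_coverage(self):
        s = self.make_sample(["CASSQETQYFFF", "CASSQETQYAFF"])
        cl = MotifCluster("QET", frozenset(r.key for r in s.records), 1e-9, 2, 0, 2, 100)
        assert enriched_motif_summary([cl], s) == (1.0, 1.0)

    def test_overlapping_clusters_not_double_counted(self):
        s = self.make_sample(["CASSQETQYFFF", "CASSQETQYAFF", "CASSWWWWWWFF"])
        keys = [r.key for r in s.records]
        cl1 = MotifCluster("QET", frozenset(keys[:2]), 1e-9, 2, 0, 3, 100)
        cl2 = MotifCluster("ETQ", frozenset(keys[:2]), 1e-9, 2, 0, 3, 100)
        reads_frac, clone_frac = enriched_motif_summary([cl1, cl2], s)
        assert reads_frac == pytest.approx(2 / 3)
        assert clone_frac == pytest.approx(2 / 3)
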