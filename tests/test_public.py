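"""Public-clone detection, sharing, convergence and HLA stratification."""

from collections import defaultdict

import numpy as np
import pytest

from tcrtrack.core import (
    ClonotypeKey,
    ClonotypeRecord,
    CohortDataset,
    RepertoireSample,
    SubjectMeta,
    aggregate_to_aa,
)
from tcrtrack.publics import (
    convergence_counts,
    identify_public,
    sharing_distribution,
    stratify_by_hla,
)

NTS = {"CAF": "TGTGCCTTT", "CGF": "TGTGGGTTT", "CSF": "TGTAGTTTT", "CLF": "TGTCTGTTT"}


def cohort_from(spec):
    """spec: {subject: {aa: reads}} at timepoint 0, subset CD4_RO."""
    samples, subjects = [], []
    for sid, clones in spec.items():
        recs = [
            ClonotypeRecord(ClonotypeKey("TRBV1", "TRBJ1", aa), NTS[aa], reads)
            for aa, reads in clones.items()
        ]
        samples.append(RepertoireSample(sid, 0, "CD4_RO", recs))
        subjects.append(SubjectMeta(sid))
    return CohortDataset(samples=samples, subjects=subjects)


def brute_force_public(cohort, subset, tp, min_reads, min_subjects):
    """Independent double-loop oracle."""
    out = {}
    keys = set()
    for s in cohort.samples:
        if s.subset == subset and s.timepoint_months == tp:
            keys |= set(aggregate_to_aa(s))
    for key in keys:
        subs = set()
        for s in cohort.samples:
            if s.subset != subset or s.timepoint_months != tp:
                continue
            reads = sum(r.read_count for r in s.records if r.key == key)
            if reads >= min_reads:
                subs.add(s.subject_id)
        if len(subs) >= min_subjects:
            out[key] = frozenset(subs)
    return out


class TestIdentify:
    def test_rule_applied(self):
        c = cohort_from({"A": {"CAF": 3}, "B": {"CAF": 2}, "C": {"CGF": 9}})
        public = identify_public(c, "CD4_RO", 0)
        assert public == {ClonotypeKey("TRBV1", "TRBJ1", "CAF"): frozenset({"A", "B"})}

    def test_per_subject_threshold_strict(self):
        c = cohort_from({"A": {"CAF": 1}, "B": {"CAF": 5}})
        assert identify_public(c, "CD4_RO", 0) == {}

    def test_pooled_threshold_alternative(self):
        c = cohort_from({"A": {"CAF": 1}, "B": {"CAF": 5}})
        public = identify_public(c, "CD4_RO", 0, per_subject_threshold=False)
        assert set(public) == {ClonotypeKey("TRBV1", "TRBJ1", "CAF")}

    def test_matches_brute_force_on_random_cohorts(self):
        rng = np.random.default_rng(4)
        aas = list(NTS)
        for _ in range(30):
            spec = {
                f"S{i}": {
                    aa: int(rng.integers(0, 6))
                    for aa in aas
                    if rng.random() < 0.7
                }
                for i in range(4)
            }
            spec = {s: {a: r for a, r in cl.items() if r > 0} for s, cl in spec.items()}
            c = cohort_from(spec)
            for min_reads in (1, 2, 3):
                for min_subjects in (2, 3):
                    assert identify_public(
                        c, "CD4_RO", 0, min_reads, min_subjects
                    ) == brute_force_public(c, "CD4_RO", 0, min_reads, min_subjects)

    def test_monotone_in_thresholds(self):
        c = cohort_from(
            {"A": {"CAF": 3, "CGF": 2}, "B": {"CAF": 2, "CGF": 1}, "C": {"CAF": 4}}
        )
        loose = set(identify_public(c, "CD4_RO", 0, min_reads=1))
        strict = set(identify_public(c, "CD4_RO", 0, min_reads=3))
        assert strict <= loose
        few = set(identify_public(c, "CD4_RO", 0, min_subjects=3))
        assert few <= set(identify_public(c, "CD4_RO", 0, min_subjects=2))

    def test_needs_two_subjects(self):
        c = cohort_from({"A": {"CAF": 3}})
        with pytest.raises(ValueError):
            identify_public(c, "CD4_RO", 0)


class TestSharing:
    def test_counts(self):
        m = {
            ClonotypeKey("V", "J", "CAF"): frozenset({"A", "B"}),
            ClonotypeKey("V", "J", "CGF"): frozenset({"A", "B"}),
            ClonotypeKey("V", "J", "CSF"): frozenset({"A", "B", "C"}),
        }
        d = sharing_distribution(m)
        assert d[frozenset({"A", "B"})] == 2
        assert d[frozenset({"A", "B", "C"})] == 1

    def test_empty(self):
        assert sharing_distribution({}) == {}

    def test_totals_conserved(self, small_cohort):
        cohort, _ = small_cohort
        public = identify_public(cohort, "CD4_RO", 0)
        d = sharing_distribution(public)
        assert sum(d.values()) == len(public)


class TestConvergence:
    def test_variant_counts(self):
        recs = [
            ClonotypeRecord(ClonotypeKey("V", "J", "CAF"), "TGTGCCTTT", 2),
            ClonotypeRecord(ClonotypeKey("V", "J", "CAF"), "TGCGCCTTC", 1),
            ClonotypeRecord(ClonotypeKey("V", "J", "CAF"), "TGTGCATTT", 1),
            ClonotypeRecord(ClonotypeKey("V", "J", "CGF"), "TGTGGGTTT", 5),
        ]
        s = RepertoireSample("A", 0, "CD4_RO", recs)
        counts = convergence_counts(s, list({r.key for r in recs}))
        assert counts[ClonotypeKey("V", "J", "CAF")] == 3
        assert counts[ClonotypeKey("V", "J", "CGF")] == 1

    def test_absent_key_warns_zero(self):
        s = RepertoireSample("A", 0, "CD4_RO", [])
        with pytest.warns(UserWarning):
            counts = convergence_counts(s, [ClonotypeKey("V", "J", "CAF")])
        assert counts[ClonotypeKey("V", "J", "CAF")] == 0

    def test_matches_simulator_registry(self, small_cohort):
        cohort, truth = small_cohort
        for pc in truth.public_registry:
            for sid in pc.subjects:
                s = cohort.get_sample(sid, 0, pc.subset)
                counts = convergence_counts(s, [pc.key])
                assert counts[pc.key] == len(pc.encodings)


class TestHlaStratification:
    def cohort(self):
        samples, subjects = [], []
        alleles = {
            "A": {"DRB1*15:01", "A*02:01"},
            "B": {"DRB1*15:01"},
            "C": {"DRB1*04:01"},
            "D": {"A*01:01"},
            "E": {"DRB1*15:03"},
        }
        for sid, al in alleles.items():
            subjects.append(SubjectMeta(sid, frozenset(al)))
            samples.append(
                RepertoireSample(
                    sid, 0, "CD4_RO",
                    [ClonotypeRecord(ClonotypeKey("V", "J", "CAF"), NTS["CAF"], 2)],
                )
            )
        return CohortDataset(samples=samples, subjects=subjects)

    def test_partition(self):
        pos, neg = stratify_by_hla(self.cohort(), "DRB1*15:01")
        assert {s.subject_id for s in pos.subjects} == {"A", "B"}
        assert {s.subject_id for s in neg.subjects} == {"C", "D", "E"}

    def test_prefix_resolution(self):
        pos, _ = stratify_by_hla(self.cohort(), "DRB1*15")
        assert {s.subject_id for s in pos.subjects} == {"A", "B", "E"}

    def test_absent_allele(self):
        pos, neg = stratify_by_hla(self.cohort(), "B*57:01")
        assert pos.subjects == [] and len(neg.subjects) == 5

    def test_partition_exhaustive_disjoint(self):
        c = self.cohort()
        pos, neg = stratify_by_hla(c, "DRB1*15:01")
        ids = {s.subject_id for s in pos.subjects} | {s.subject_id for s in neg.subjects}
        assert ids == {s.subject_id for s in c.subjects}
        assert not ({s.subject_id for s in pos.subjects} & {s.subject_id for s in neg.subjects})

    def test_malformed_allele(self):
        with pytest.raises(ValueError):
            stratify_by_hla(self.cohort(), "DRB115")
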