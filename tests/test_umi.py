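"""UMI extraction, directional collapse, CDR3 calling, read pipeline."""

import numpy as np
import pytest
from Bio.Seq import Seq

from tcrtrack import vdj
from tcrtrack.simulate import PublicSpec, SimulationConfig, simulate_cohort, simulate_reads
from tcrtrack.umi import (
    FRAME,
    NO_ADAPTER,
    NO_V,
    ReadStructure,
    UmiGroup,
    build_clonotype_table,
    call_cdr3,
    collapse_umis,
    extract_umi,
)

STRUCT = ReadStructure()


class TestExtract:
    def test_constructed_read(self):
        read = STRUCT.adapter + "ACGTACGTAC" + STRUCT.spacer + "TGTGCCTTT"
        ext = extract_umi(read, STRUCT)
        assert ext.ok and ext.umi == "ACGTACGTAC" and ext.insert == "TGTGCCTTT"

    def test_one_adapter_mismatch_tolerated(self):
        adapter = "A" + STRUCT.adapter[1:]
        ext = extract_umi(adapter + "ACGTACGTAC" + STRUCT.spacer + "TGT", STRUCT)
        assert ext.ok

    def test_missing_adapter(self):
        assert extract_umi("T" * 80, STRUCT).rejection == NO_ADAPTER

    def test_too_short(self):
        ext = extract_umi(STRUCT.adapter + "ACGTA", STRUCT)
        assert ext.rejection == "too_short"

    def test_bad_spacer(self):
        read = STRUCT.adapter + "ACGTACGTAC" + "TTTTTTT" + "TGTGCC"
        assert extract_umi(read, STRUCT).rejection == "no_spacer"

    def test_extraction_error_rate_matches_theory(self):
        """Fraction of extracted reads with the correct UMI tracks the
        per-base substitution model (0.999^10) within Monte-Carlo error."""
        rng = np.random.default_rng(77)
        e = 0.001
        n = 4000
        correct = extracted = 0
        umi = "ACGTACGTAC"
        template = STRUCT.adapter + umi + STRUCT.spacer + "TGTGCCGGGACAGGGGAACACGTTT"
        arr = np.frombuffer(template.encode(), dtype=np.uint8).copy()
        for _ in range(n):
            read = list(template)
            for pos in np.nonzero(rng.random(len(read)) < e)[0]:
                read[pos] = "ACGT"[(("ACGT".index(read[pos])) + rng.integers(1, 4)) % 4]
            ext = extract_umi("".join(read), STRUCT)
            if ext.ok:
                extracted += 1
                correct += ext.umi == umi
        frac = correct / extracted
        expect = 0.999**10
        se = np.sqrt(expect * (1 - expect) / extracted)
        assert abs(frac - expect) < 4 * se + 1e-9


class TestCollapse:
    def test_directional_merge(self):
        a = UmiGroup("A" * 10, 10)
        b = UmiGroup("A" * 9 + "T", 1)
        out = collapse_umis([a, b])
        assert len(out) == 1 and out[0].read_count == 11

    def test_distance_two_not_merged(self):
        out = collapse_umis([UmiGroup("A" * 10, 10), UmiGroup("A" * 8 + "TT", 1)])
        assert len(out) == 2

    def test_count_rule_blocks_merge(self):
        # 4 >= 2*3-1 is false: peers stay separate
        out = collapse_umis([UmiGroup("A" * 10, 4), UmiGroup("A" * 9 + "T", 3)])
        assert len(out) == 2

    def test_order_independence(self):
        rng = np.random.default_rng(3)
        groups = [
            UmiGroup("AAAAAAAAAA", 40),
            UmiGroup("AAAAAAAAAT", 2),
            UmiGroup("AAAAAAAATT", 1),
            UmiGroup("CCCCCCCCCC", 9),
            UmiGroup("CCCCCCCCCT", 4),
        ]
        ref = sorted((g.umi, g.read_count) for g in collapse_umis(groups))
        for _ in range(5):
            perm = list(groups)
            rng.shuffle(perm)
            perm = [UmiGroup(g.umi, g.read_count) for g in perm]
            assert sorted((g.umi, g.read_count) for g in collapse_umis(perm)) == ref

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            collapse_umis([UmiGroup("AAAA", 1), UmiGroup("AAAAA", 1)])

    def test_known_molecule_counts_recovered(self):
        """Collapsed counts equal the true molecule number for >=99% of
        clonotypes under 0.3% per-base UMI errors."""
        rng = np.random.default_rng(5)
        exact = 0
        n_clones = 300
        for _ in range(n_clones):
            n_mol = int(rng.integers(1, 8))
            groups = {}
            umis = []
            while len(umis) < n_mol:
                u = "".join("ACGT"[i] for i in rng.integers(0, 4, 10))
                if u not in umis:
                    umis.append(u)
            for u in umis:
                n_reads = 1 + rng.poisson(3)
                for _ in range(n_reads):
                    read_umi = list(u)
                    for pos in np.nonzero(rng.random(10) < 0.003)[0]:
                        read_umi[pos] = "ACGT"[rng.integers(4)]
                    read_umi = "".join(read_umi)
                    groups[read_umi] = groups.get(read_umi, 0) + 1
            collapsed = collapse_umis([UmiGroup(u, c) for u, c in groups.items()])
            exact += len(collapsed) == n_mol
        assert exact / n_clones >= 0.99


class TestCallCdr3:
    def test_inverts_simulator(self, toy):
        rng = np.random.default_rng(31)
        called = 0
        for nt, sc in vdj.sample_rearrangements(toy, 200, rng):
            if not vdj.is_productive(nt):
                continue
            res = call_cdr3(nt, toy)
            assert not isinstance(res, str), f"{nt} rejected: {res}"
            key, got_nt = res
            assert got_nt == nt
            assert key.v_gene == toy.v_names[sc.v_choice]
            assert key.j_gene == toy.j_names[sc.j_choice]
            called += 1
        assert called >= 50

    def test_frame_rejection(self, toy):
        nt, _ = vdj.sample_rearrangement(toy, 11)
        while len(nt) % 3 == 0:
            nt = nt + "G"
        assert call_cdr3(nt, toy) == FRAME

    def test_no_v_rejection(self, toy):
        assert call_cdr3("TTTTTTTTTTTTTTTTTT", toy) == NO_V


class TestBuildTable:
    def test_single_molecule_many_reads(self, toy):
        nt, sc = None, None
        for nt_c, sc_c in vdj.sample_rearrangements(toy, 100, 1):
            if vdj.is_productive(nt_c):
                nt, sc = nt_c, sc_c
                break
        read = STRUCT.adapter + "ACGTACGTAC" + STRUCT.spacer + nt
        sample, qc = build_clonotype_table([read] * 100, STRUCT, toy)
        (rec,) = sample.records
        assert rec.read_count == 100 and rec.umi_count == 1
        assert qc.assigned == 100 and qc.total == 100

    def test_empty_input(self, toy):
        sample, qc = build_clonotype_table([], STRUCT, toy)
        assert sample.records == [] and qc.total == 0

    def test_totals_conserved_with_errors(self, toy):
        cfg = SimulationConfig(
            n_subjects=1, subsets=("CD4_RO",), timepoints=(0,),
            clones_per_sample=80, umis_per_sample=800,
            public=PublicSpec(n_public=0), seed=2,
        )
        cohort, _ = simulate_cohort(cfg)
        s = cohort.samples[0]
        reads = list(simulate_reads(s, STRUCT, 9, error_rate=0.002))
        built, qc = build_clonotype_table((seq for _, seq in reads), STRUCT, toy)
        assert qc.total == len(reads)
        assert qc.assigned == sum(r.read_count for r in built.records)
        for r in built.records:
            assert r.umi_count <= r.read_count
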