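"""Generative-model correctness: sampler, P_GEN dynamic programs, oracles."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq
from scipy import stats as sps

from tcrtrack import vdj
from tcrtrack.vdj import (
    CODONS_FOR_AA,
    GenerativeModel,
    ModelError,
    enumerate_scenarios,
    enumerate_sequence_space,
    is_productive,
    pgen_aa,
    pgen_nt,
    sample_rearrangement,
    sample_rearrangements,
)


class TestDegenerateModel:
    def test_only_realizable_string(self, degenerate):
        nt, sc = sample_rearrangement(degenerate, 0)
        assert nt == "TGTTTT"
        assert pgen_nt(degenerate, "TGTTTT") == pytest.approx(1.0, abs=1e-12)
        assert pgen_nt(degenerate, "TGTATT") == 0.0

    def test_single_scenario(self, degenerate):
        scen = enumerate_scenarios(degenerate, "TGTTTT")
        assert len(scen) == 1
        assert scen[0][1] == pytest.approx(1.0, abs=1e-12)
        assert enumerate_scenarios(degenerate, "TGTATT") == []

    def test_aa_marginal_collapses(self, degenerate):
        # "CF" is coded by TGT/TGC x TTT/TTC but the model realizes only TGTTTT
        assert pgen_aa(degenerate, "CF") == pytest.approx(1.0, abs=1e-12)


class TestSampler:
    def test_seed_determinism(self, toy):
        a = [sample_rearrangement(toy, s)[0] for s in range(5)]
        b = [sample_rearrangement(toy, s)[0] for s in range(5)]
        assert a == b

    def test_batch_matches_structure(self, toy):
        for nt, sc in sample_rearrangements(toy, 50, 3):
            assert nt == sc.realize(toy)
            assert sc.probability(toy) > 0

    def test_sampler_agrees_with_pgen(self, tiny):
        """Empirical frequencies match pgen within Monte-Carlo error."""
        n = 20_000
        rng = np.random.default_rng(123)
        draws = [nt for nt, _ in sample_rearrangements(tiny, n, rng)]
        seqs, counts = np.unique(draws, return_counts=True)
        probs = np.array([pgen_nt(tiny, s) for s in seqs])
        # chi-square over observed cells plus the unobserved remainder
        expected = probs * n
        keep = expected >= 5
        chi = float(((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum())
        dof = int(keep.sum()) - 1
        p = sps.chi2.sf(chi, dof)
        assert p > 0.01


class TestPgenNt:
    def test_matches_enumeration_oracle(self, toy):
        rng = np.random.default_rng(7)
        for nt, _ in sample_rearrangements(toy, 40, rng):
            dp = pgen_nt(toy, nt)
            oracle = sum(p for _, p in enumerate_scenarios(toy, nt))
            assert dp == pytest.approx(oracle, abs=1e-12)

    def test_scenarios_unique(self, toy):
        nt, _ = sample_rearrangement(toy, 9)
        scen = enumerate_scenarios(toy, nt)
        assert len({s for s, _ in scen}) == len(scen)
        assert all(s.realize(toy) == nt for s, _ in scen)

    def test_total_mass_is_one(self, tiny):
        seqs = enumerate_sequence_space(tiny)
        total = sum(pgen_nt(tiny, s) for s in seqs)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_invalid_alphabet(self, toy):
        with pytest.raises(ValueError):
            pgen_nt(toy, "TGTNCC")

    def test_enumeration_guard(self, toy):
        with pytest.raises(ModelError, match="scenario space"):
            enumerate_scenarios(toy, "TGT" * 10, guard=10)


class TestPgenAa:
    @staticmethod
    def codon_expansion_oracle(model, aa):
        total = 0.0
        for combo in itertools.product(*[CODONS_FOR_AA[a] for a in aa]):
            total += pgen_nt(model, "".join(combo))
        return total

    def test_matches_codon_expansion(self, tiny):
        seqs = sorted(enumerate_sequence_space(tiny))
        aa_set = sorted({str(Seq(s).translate()) for s in seqs if is_productive(s)})[:15]
        for aa in aa_set:
            assert pgen_aa(tiny, aa) == pytest.approx(
                self.codon_expansion_oracle(tiny, aa), abs=1e-12
            )

    def test_dominates_any_single_coding(self, toy):
        rng = np.random.default_rng(21)
        for nt, _ in sample_rearrangements(toy, 30, rng):
            if not is_productive(nt):
                continue
            aa = str(Seq(nt).translate())
            assert pgen_aa(toy, aa) >= pgen_nt(toy, nt) - 1e-15

    def test_vj_restriction_partitions_marginal(self, toy):
        nt, _ = sample_rearrangement(toy, 4)
        total = sum(
            pgen_nt(toy, nt, v, j) for v in toy.v_names for j in toy.j_names
        )
        assert total == pytest.approx(pgen_nt(toy, nt), abs=1e-12)

    def test_invalid_letters(self, toy):
        with pytest.raises(ValueError):
            pgen_aa(toy, "CAXB")


class TestModelPlumbing:
    def test_yaml_roundtrip(self, toy, tmp_path):
        p = tmp_path / "model.yaml"
        toy.to_yaml(p)
        back = GenerativeModel.from_yaml(p)
        nt, _ = sample_rearrangement(toy, 2)
        assert pgen_nt(back, nt) == pytest.approx(pgen_nt(toy, nt), abs=1e-15)
        assert back.v_names == toy.v_names

    def test_distribution_validation(self):
        with pytest.raises(ModelError, match="sum to 1"):
            GenerativeModel(
                v_names=["V"], v_seqs=["TGT"], p_v=np.array([0.9]),
                d_names=["D"], d_seqs=["G"], p_d=np.array([1.0]),
                j_names=["J"], j_seqs=["TTT"], p_j=np.array([1.0]),
                p_del_v=np.array([[1.0]]), p_del_j=np.array([[1.0]]),
                p_del5=np.array([[0.0, 1.0]]), p_del3=np.array([[1.0]]),
                p_ins_vd=np.array([1.0]), p_ins_dj=np.array([1.0]),
                p_nt=np.array([0.25] * 4),
            )

    def test_deletion_support_validation(self):
        with pytest.raises(ModelError, match="support exceeds"):
            GenerativeModel(
                v_names=["V"], v_seqs=["TGT"], p_v=np.array([1.0]),
                d_names=["D"], d_seqs=["G"], p_d=np.array([1.0]),
                j_names=["J"], j_seqs=["TTT"], p_j=np.array([1.0]),
                p_del_v=np.array([[0.0, 0.0, 0.0, 0.0, 1.0]]),
                p_del_j=np.array([[1.0]]),
                p_del5=np.array([[0.0, 1.0]]), p_del3=np.array([[1.0]]),
                p_ins_vd=np.array([1.0]), p_ins_dj=np.array([1.0]),
                p_nt=np.array([0.25] * 4),
            )
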