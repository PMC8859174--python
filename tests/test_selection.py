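"""Selection-model features, P_POST, ratio binning, and fitting."""

import numpy as np
import pytest
from Bio.Seq import Seq

from tcrtrack import vdj
from tcrtrack.core import ClonotypeKey
from tcrtrack.selection import (
    INTERMEDIATE,
    NOT_RARE,
    RARE,
    ProbabilityAnnotation,
    SelectionModel,
    featurize,
    fit_selection,
    flag_escapees,
    ppost,
    ratio_bin,
    renormalize_exact,
)


class TestFeaturize:
    def test_definition(self):
        feats = featurize(ClonotypeKey("TRBV1", "TRBJ1", "CASF"))
        assert feats == {
            "len:4", "v:TRBV1", "j:TRBJ1",
            "l:1:C", "l:2:A", "l:3:S", "l:4:F",
            "r:4:C", "r:3:A", "r:2:S", "r:1:F",
        }

    def test_feature_count(self):
        for aa in ("CASSLGF", "CAF", "CASSQETQYF"):
            k = ClonotypeKey("V", "J", aa)
            assert len(featurize(k)) == 3 + 2 * len(aa)

    def test_positions_truncated_for_long_cdr3(self):
        aa = "C" + "A" * 20 + "F"  # 22 residues
        feats = featurize(ClonotypeKey("V", "J", aa))
        positional = [f for f in feats if f.startswith(("l:", "r:"))]
        assert all(int(f.split(":")[1]) <= 12 for f in positional)


class TestPpost:
    def test_identity_selection(self, tiny):
        model = SelectionModel()
        key = ClonotypeKey("TRBV-a", "TRBJ-a", "CAGTDSF")
        # pick a generatable key from the tiny model instead
        trips = vdj.sample_productive(tiny, 1, 5)
        v, j, nt = trips[0]
        key = ClonotypeKey(v, j, str(Seq(nt).translate()))
        a = ppost(model, tiny, key)
        assert a.ppost == pytest.approx(a.pgen, rel=1e-12)
        assert a.q_ratio == pytest.approx(1.0, rel=1e-12)
        assert a.bin == NOT_RARE

    def test_log_linearity(self, tiny):
        trips = vdj.sample_productive(tiny, 1, 6)
        v, j, nt = trips[0]
        key = ClonotypeKey(v, j, str(Seq(nt).translate()))
        f = f"v:{v}"
        m0 = SelectionModel(weights={f: 0.3})
        m1 = SelectionModel(weights={f: 1.3})
        r0 = ppost(m0, tiny, key).q_ratio
        r1 = ppost(m1, tiny, key).q_ratio
        assert r1 / r0 == pytest.approx(np.exp(1.0), rel=1e-9)

    def test_ungeneratable_flagged(self, degenerate):
        key = ClonotypeKey("V0", "J0", "WW")
        a = ppost(SelectionModel(), degenerate, key)
        assert a.ungeneratable and a.pgen == 0.0 and a.ppost == 0.0

    def test_normalization_over_key_space(self, tiny):
        """Sum of P_POST over the full productive key space is 1 after
        exact renormalization of a fitted model."""
        seqs = enumerated = sorted(vdj.enumerate_sequence_space(tiny))
        keyspace = {}
        for s in seqs:
            if not vdj.is_productive(s):
                continue
            aa = str(Seq(s).translate())
            for v in tiny.v_names:
                for j in tiny.j_names:
                    key = ClonotypeKey(v, j, aa)
                    if key not in keyspace:
                        pg = vdj.pgen_aa(tiny, aa, v, j)
                        if pg > 0:
                            keyspace[key] = pg
        obs = vdj.sample_productive(tiny, 600, 3)
        obs_keys = [ClonotypeKey(v, j, str(Seq(nt).translate())) for v, j, nt in obs]
        fitted = fit_selection(tiny, obs_keys, baseline_size=3000, rng_seed=4)
        exact = renormalize_exact(fitted, keyspace.keys(), keyspace.values())
        total = sum(pg * exact.q(k) for k, pg in keyspace.items())
        assert total == pytest.approx(1.0, abs=1e-6)


class TestRatioBin:
    @pytest.mark.parametrize(
        "ratio,expected",
        [
            (0.5, NOT_RARE),
            (5e-5, RARE),
            (0.1, NOT_RARE),           # boundary goes to the upper class
            (1e-4, INTERMEDIATE),
            (np.nextafter(0.1, 0), INTERMEDIATE),
            (np.nextafter(1e-4, 0), RARE),
            (np.nextafter(0.1, 1), NOT_RARE),
            (np.nextafter(1e-4, 1), INTERMEDIATE),
        ],
    )
    def test_boundaries(self, ratio, expected):
        assert ratio_bin(1.0, ratio) == expected

    def test_requires_positive_pgen(self):
        with pytest.raises(ValueError):
            ratio_bin(0.0, 1e-5)

    def test_pure_function_of_ratio(self):
        assert ratio_bin(1e-6, 1e-6 * 0.02) == ratio_bin(0.5, 0.01)


class TestEscapees:
    def mk(self, pgen, ppost_val):
        b = ratio_bin(pgen, ppost_val)
        return ProbabilityAnnotation(
            ClonotypeKey("V", "J", "CAF"), pgen, ppost_val, ppost_val / pgen,
            b, escapee=(b == RARE),
            low_ppost=bool(ppost_val > 0 and np.log10(ppost_val) < -10),
        )

    def test_flagging(self):
        flagged = flag_escapees([self.mk(1e-6, 1e-11), self.mk(1e-6, 2e-7)])
        assert len(flagged) == 1
        assert flagged[0].low_ppost is True

    def test_subset_of_rare(self):
        anns = [self.mk(1e-6, x * 1e-6) for x in (0.5, 0.01, 5e-5, 1e-9)]
        assert all(a.bin == RARE for a in flag_escapees(anns))

    def test_empty(self):
        assert flag_escapees([]) == []


class TestFit:
    def test_strong_l2_shrinks_to_zero(self, tiny):
        obs = vdj.sample_productive(tiny, 300, 9)
        keys = [ClonotypeKey(v, j, str(Seq(nt).translate())) for v, j, nt in obs]
        m = fit_selection(tiny, keys, baseline_size=1500, l2=1e4, rng_seed=1)
        assert max(abs(w) for w in m.weights.values()) < 1e-3

    def test_null_weights_small(self, toy):
        obs = vdj.sample_productive(toy, 3000, 17)
        keys = [ClonotypeKey(v, j, str(Seq(nt).translate())) for v, j, nt in obs]
        m = fit_selection(toy, keys, baseline_size=30_000, rng_seed=18)
        assert m.fit_info["converged"]
        assert max(abs(w) for w in m.weights.values()) < 0.15

    def test_deterministic_given_seed(self, tiny):
        obs = vdj.sample_productive(tiny, 200, 2)
        keys = [ClonotypeKey(v, j, str(Seq(nt).translate())) for v, j, nt in obs]
        m1 = fit_selection(tiny, keys, baseline_size=1000, rng_seed=5)
        m2 = fit_selection(tiny, keys, baseline_size=1000, rng_seed=5)
        assert m1.weights == m2.weights and m1.log_z == m2.log_z

    def test_empty_observed_rejected(self, tiny):
        with pytest.raises(ValueError):
            fit_selection(tiny, [], baseline_size=100)

    def test_json_roundtrip(self, tiny, tmp_path):
        obs = vdj.sample_productive(tiny, 100, 8)
        keys = [ClonotypeKey(v, j, str(Seq(nt).translate())) for v, j, nt in obs]
        m = fit_selection(tiny, keys, baseline_size=500, rng_seed=5)
        p = tmp_path / "sel.json"
        m.to_json(p)
        back = SelectionModel.from_json(p)
        assert back.weights == m.weights and back.log_z == m.log_z
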