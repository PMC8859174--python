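import numpy as np
import pytest

from tcrtrack import vdj
from tcrtrack.simulate import PublicSpec, SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def toy():
    return vdj.toy_model()


@pytest.fixture(scope="session")
def tiny():
    return vdj.tiny_model()


@pytest.fixture(scope="session")
def degenerate():
    """A model that generates exactly one string: TGT + TTT."""
    return vdj.GenerativeModel(
        v_names=["V0"], v_seqs=["TGT"], p_v=np.array([1.0]),
        d_names=["D0"], d_seqs=["A"], p_d=np.array([1.0]),
        j_names=["J0"], j_seqs=["TTT"], p_j=np.array([1.0]),
        p_del_v=np.array([[1.0]]), p_del_j=np.array([[1.0]]),
        p_del5=np.array([[0.0, 1.0]]), p_del3=np.array([[1.0]]),
        p_ins_vd=np.array([1.0]), p_ins_dj=np.array([1.0]),
        p_nt=np.array([0.25, 0.25, 0.25, 0.25]),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small longitudinal cohort with injected public clones."""
    cfg = SimulationConfig(
        n_subjects=5,
        subsets=("CD4_RO",),
        clones_per_sample=150,
        umis_per_sample=4000,
        public=PublicSpec(n_public=12),
        seed=11,
    )
    return simulate_cohort(cfg)
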