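import numpy as np
import pytest

from cbss.algorithms import RunConfig, reduce_cohort, run
from cbss.constraints import ReferenceSet
from cbss.simdata import SimConfig, simulate_cohort

STUDY_CFG = SimConfig(K=10, N=8, V=5000, M=6, scv_corr=0.5, ref_corr=0.9, seed=1)
TINY_CFG = SimConfig(K=4, N=5, V=1500, M=3, scv_corr=0.5, ref_corr=0.9, seed=3)


@pytest.fixture(scope="session")
def study_cohort():
    """Reference-guided study cohort: K=10 subjects, 8 components, 6 references."""
    gt, data = simulate_cohort(STUDY_CFG)
    reduced = reduce_cohort(data, STUDY_CFG.N)
    return STUDY_CFG, gt, reduced, ReferenceSet(gt.references)


@pytest.fixture(scope="session")
def study_runs(study_cohort):
    """One full run of each solver on the study cohort (shared seed)."""
    _, _, reduced, refs = study_cohort
    return {
        algo: run(reduced, refs, RunConfig(algorithm=algo, seed=7))
        for algo in ("ar-civa", "tf-civa", "ar-cebm")
    }


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small cohort for fast solver unit tests."""
    gt, data = simulate_cohort(TINY_CFG)
    reduced = reduce_cohort(data, TINY_CFG.N)
    return TINY_CFG, gt, reduced, ReferenceSet(gt.references)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
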