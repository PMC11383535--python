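import numpy as np
import pytest

from itemrsa import simulate as sm
from itemrsa.rsm import FeatureNorms


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_norms() -> FeatureNorms:
    """Deterministic 6-concept, 4+3-feature norms with full coverage."""
    rng = np.random.default_rng(7)
    values = rng.uniform(0.05, 1.0, size=(6, 7))
    cats = np.array(["visual"] * 4 + ["semantic"] * 3)
    return FeatureNorms(
        [f"c{i}" for i in range(6)], [f"f{j}" for j in range(7)], cats, values
    )


@pytest.fixture
def small_study() -> sm.SyntheticStudy:
    norms = sm.gen_feature_norms(25, 14, 10, cross_corr=0.3, seed=11)
    design = sm.StudyDesign(
        n_participants=3, n_old=15, n_catch=2, n_new=5,
        roi_spec=[("otc-1", "OTC", 30), ("ipc-1", "IPC", 30)],
    )
    truth = sm.uniform_effects(0.8, 0.4, noise_sd=1.0)
    return sm.gen_study(design, truth, norms, seed=21)
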