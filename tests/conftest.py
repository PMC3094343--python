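import numpy as np
import pytest

from qkforest import simdata


def make_markers(scores, **kw):
    scores = np.asarray(scores)
    n, m = scores.shape
    kw.setdefault("accession_ids", [f"a{i}" for i in range(n)])
    kw.setdefault("marker_names", [f"m{j}" for j in range(m)])
    return simdata.MarkerMatrix(scores=scores, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_markers(rng):
    """60 accessions x 40 polymorphic markers, no all-zero rows."""
    scores = (rng.random((60, 40)) < rng.uniform(0.2, 0.8, 40)).astype(np.int8)
    scores[:, 0] = 1  # guarantee no empty profile
    return make_markers(scores)


@pytest.fixture
def structured_dataset():
    """Two-subpopulation collection with confounded phenotype and truth."""
    cfg = simdata.SimConfig(n_accessions=120, n_subpops=2, fst=0.25,
                            admix_alpha=0.1, n_markers=150,
                            pop_effects=[1.0, -1.0], sigma_g2=0.3,
                            sigma_e2=0.7, seed=42)
    markers, pheno, truth = simdata.simulate_dataset(cfg)
    return cfg, markers, pheno, truth
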