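import numpy as np
import pytest

import edphylo as e


@pytest.fixture(scope="session")
def paper_table():
    return e.load_paper_table()


@pytest.fixture(scope="session")
def standin_tree():
    return e.load_standin_tree()


@pytest.fixture()
def cherry():
    return e.parse_newick("(A:1,B:1);")


@pytest.fixture()
def three_leaf():
    return e.parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture()
def balanced_four():
    return e.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


def fit_simulated(seed, true_beta, true_lambda, n_tips=100, sigma2=25.0,
                  options=None):
    """Simulate one regression dataset and fit it; shared by recovery tests."""
    cfg = e.SimulationConfig(
        n_tips=n_tips,
        true_lambda=true_lambda,
        true_beta=tuple(true_beta),
        sigma2=sigma2,
        seed=seed,
    )
    tree, traits, truth = e.simulate_regression_dataset(cfg)
    V = e.vcv_matrix(tree, traits["species"])
    X = e.DesignMatrix.build(
        traits["species"].tolist(),
        {c: traits[c].to_numpy(float)
         for c in ("clutch_size", "foraging", "activity", "nest")},
    )
    y = traits["edp_residual"].to_numpy(float)
    return e.fit_pgls(y, X, V, options), truth
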