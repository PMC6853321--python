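import numpy as np
import pytest

import pooltrend as pt
from pooltrend.models import ModelDefinition, PosteriorDraws
from pooltrend.synthetic import study_like_params


@pytest.fixture(scope="session")
def design():
    return pt.default_design()


@pytest.fixture(scope="session")
def planted_interaction_params():
    """Model-1 truth with age-diverging temporal slopes (age-by-time interaction)."""
    beta_at = np.array([3.0 + s * np.arange(1, 6) for s in (-0.3, -0.15, 0.0, 0.15, 0.3)])
    return pt.GenerativeParams(1, sigma=0.3, beta_at=beta_at)


@pytest.fixture(scope="session")
def planted_interaction_data(design, planted_interaction_params):
    return pt.simulate_dataset(design, planted_interaction_params, seed=3)


@pytest.fixture(scope="session")
def brt_fit_planted(planted_interaction_data):
    return pt.fit_brt(
        planted_interaction_data, shrinkage=0.05, max_trees=800, tree_depth=3, split_seed=3
    )


@pytest.fixture(scope="session")
def study_data(design):
    return pt.simulate_dataset(design, study_like_params(), seed=42)


@pytest.fixture(scope="session")
def model3():
    return pt.build_model(3)


@pytest.fixture(scope="session")
def draws3(model3, study_data):
    return pt.sample_posterior(model3, study_data, n_iter=1500, n_burnin=1500, seed=7)


@pytest.fixture(scope="session")
def model1():
    return pt.build_model(1)


@pytest.fixture(scope="session")
def draws1(model1, study_data):
    return pt.sample_posterior(model1, study_data, n_iter=1000, n_burnin=1000, seed=7)


def make_degenerate_draws(
    model: ModelDefinition, values: dict[str, float], n_iter: int = 50, n_chains: int = 2
) -> PosteriorDraws:
    """A posterior whose every draw equals the same packed parameter vector."""
    vec = np.array([values[name] for name in model.param_names], dtype=float)
    draws = np.broadcast_to(vec, (n_chains, n_iter, len(vec))).copy()
    return PosteriorDraws(draws=draws, param_names=model.param_names, n_burnin=0, seed=0)


def degenerate_values(model: ModelDefinition, cell_mean: float, sigma: float) -> dict[str, float]:
    """Parameter assignment making every grid cell's mean equal `cell_mean`."""
    vals: dict[str, float] = {}
    for name in model.param_names:
        if name == "sigma":
            vals[name] = sigma
        elif name in ("omega", "phi"):
            vals[name] = 1.0
        elif name.startswith("beta0") or name.startswith("delta") or name.startswith("alpha_g"):
            vals[name] = 0.0
        elif name.startswith("beta") and model.spec == 3:
            vals[name] = 0.0
        elif name.startswith(("beta", "alpha")):
            vals[name] = cell_mean
        else:
            vals[name] = 0.0
    return vals
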