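"""Shared fixtures: a seeded synthetic cohort and derived pipeline objects.

Session-scoped because the factorization fixtures are the expensive part;
every test treats them as read-only.
"""

import numpy as np
import pandas as pd
import pytest

from txfeedback import (SimConfig, apply_uncertainty_floor, collapse_probes,
                        condition_stats, factorize, filter_genes,
                        generate_truth, simulate_expression)
from txfeedback.preprocess import FactorInput


@pytest.fixture(scope="session")
def sim_cfg():
    return SimConfig(seed=42)


@pytest.fixture(scope="session")
def truth(sim_cfg):
    return generate_truth(sim_cfg)


@pytest.fixture(scope="session")
def bundle(truth, sim_cfg):
    return simulate_expression(truth, sim_cfg)


@pytest.fixture(scope="session")
def collapsed(bundle):
    return collapse_probes(bundle)


@pytest.fixture(scope="session")
def factor_input(collapsed, truth):
    fi = condition_stats(collapsed)
    fi = apply_uncertainty_floor(fi)
    return filter_genes(fi, truth.tf_targets)


@pytest.fixture(scope="session")
def fit_result(factor_input):
    """One seeded factorization with enough draws for z-scores."""
    return factorize(factor_input, 3, seed=7, n_draws=30)


@pytest.fixture(scope="session")
def zero_noise():
    """Noise-free cohort for exactness checks."""
    cfg = SimConfig(seed=7, noise_sd=0.0)
    t = generate_truth(cfg)
    b = simulate_expression(t, cfg)
    return cfg, t, b


def make_factor_input(D: np.ndarray, sigma: float = 0.1) -> FactorInput:
    """Wrap a plain matrix as a FactorInput with uniform uncertainty."""
    D = pd.DataFrame(np.asarray(D, dtype=float))
    meta = pd.DataFrame({"background": "x", "treatment": "y"}, index=D.columns)
    return FactorInput(D=D, Sigma=pd.DataFrame(np.full(D.shape, sigma),
                                               index=D.index, columns=D.columns),
                       condition_meta=meta)
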