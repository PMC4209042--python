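import logging

import numpy as np
import pytest

import lassoval as lv

logging.getLogger("lassoval").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def sim_config():
    return lv.default_config(n_obs=250)


@pytest.fixture(scope="session")
def cohort(sim_config):
    """One complete simulated cohort, n=250."""
    return lv.simulate_complete(sim_config, seed=101)


@pytest.fixture(scope="session")
def incomplete_cohort(sim_config, cohort):
    return lv.apply_mcar(cohort, sim_config.miss_probs, seed=102)


@pytest.fixture(scope="session")
def imputed_small(incomplete_cohort):
    """Three completed copies of the incomplete cohort (kept small: the
    chained-equations sweep dominates test time)."""
    return lv.impute(incomplete_cohort, m=3, n_cycles=3, seed=103)


@pytest.fixture(scope="session")
def big_draw(sim_config):
    """A large complete draw (n=200000) with the latent matrix, shared by the
    large-sample distributional checks."""
    from dataclasses import replace

    cfg = replace(sim_config, n_obs=200_000)
    ds, latent = lv.simulate_complete(cfg, seed=104, return_latent=True)
    return cfg, ds, latent


def toy_dataset(X, y, binary_cols=()):
    """Build a complete Dataset from plain arrays."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    values = np.column_stack([X, y])
    cols = [f"x{j + 1}" for j in range(X.shape[1])] + ["y"]
    types = ["binary" if j in binary_cols else "continuous" for j in range(X.shape[1])]
    types.append("continuous")
    return lv.Dataset(values, np.ones_like(values, dtype=bool), cols, types)
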