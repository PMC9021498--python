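import numpy as np
import pytest

from lidm import (
    FitConfig,
    LatentInterdependenceModel,
    SimConfig,
    draw_parameters,
    generate_dataset,
    trust_survey_example,
)


@pytest.fixture(scope="session")
def trust_table():
    return trust_survey_example()


def make_sim(n=6, model=1, seed=0, **kw):
    """One simulated (truth, table) pair under the default design."""
    cfg = SimConfig(n_members=n, model=model, **kw)
    params = draw_parameters(cfg, seed)
    table = generate_dataset(params, cfg, seed + 10_000)
    return cfg, params, table


@pytest.fixture(scope="session")
def small_fit_m1():
    """A single reduced fit of Model 1 on its own data (n=8), reused by
    several tests to keep the suite fast."""
    _, params, table = make_sim(n=8, model=1, seed=42)
    res = LatentInterdependenceModel(table, model=1).fit(
        FitConfig.reduced(seed=7))
    return params, res


@pytest.fixture(scope="session")
def small_fit_m2():
    _, params, table = make_sim(n=6, model=2, seed=43)
    res = LatentInterdependenceModel(table, model=2).fit(
        FitConfig.reduced(seed=8))
    return params, res
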