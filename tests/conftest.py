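import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import regionforce as rf

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def tiny_strata() -> rf.StrataConfig:
    """2 age bands x 2 sexes x 2 morbidity levels = 8 strata."""
    return rf.StrataConfig(
        age_bands=("young", "old"), sexes=("F", "M"), morbidity_levels=("low", "high")
    )


@pytest.fixture
def small_region(tiny_strata) -> rf.Region:
    return rf.generate_region(
        n_neighbourhoods=6, n_subregions=2, strata_config=tiny_strata, seed=11,
        mean_population=500.0,
    )


@pytest.fixture
def small_rates(tiny_strata) -> rf.NeedsRateTable:
    return rf.generate_needs_rates(tiny_strata, seed=11)


def random_flow_matrix(ids, rng, external_scale: float = 0.0) -> rf.FlowMatrix:
    """A random row-stochastic flow matrix over the given neighbourhood ids."""
    n = len(ids)
    P = rng.dirichlet(np.ones(n), size=n)
    external = rng.uniform(0, external_scale, n) if external_scale else np.zeros(n)
    return rf.FlowMatrix(tuple(ids), P, external)


def zero_umn(ids) -> rf.UnmetNeedEstimate:
    series = pd.Series(0.0, index=list(ids), name="umn")
    return rf.UnmetNeedEstimate(series, pd.DataFrame({"zero": series}))


def umn_from_series(series: pd.Series) -> rf.UnmetNeedEstimate:
    return rf.UnmetNeedEstimate(series.rename("umn"), pd.DataFrame({"fixed": series}))
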