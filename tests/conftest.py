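import numpy as np
import pandas as pd
import pytest

from sdqmap.geography import GeographyConfig, generate_geography
from sdqmap.mcmc import InferenceConfig
from sdqmap.synthetic import PopulationConfig, TruthParams, generate_children


@pytest.fixture(scope="session")
def geo21():
    return generate_geography(GeographyConfig(n_wards=21, seed=7))


@pytest.fixture(scope="session")
def small_study(geo21):
    """3,000 children, 40 preschools, default (study-like) truth."""
    pop = PopulationConfig(n_children=3000, n_preschools=40, seed=11)
    records, ledger = generate_children(geo21, pop, TruthParams())
    return records, ledger


@pytest.fixture(scope="session")
def fast_inf():
    return InferenceConfig(chains=2, warmup=600, draws=600, seed=0)


def simulate_dm_counts(seed: int, *, n_wards: int = 21, n_cohorts: int = 8,
                       b0: float = np.log(0.077), b1: float = np.log(1.033),
                       sigma2_ward: float = 0.026,
                       sigma2_slope: float = 0.0,
                       e_low: int = 150, e_high: int = 280,
                       covariate_effect: float = 0.0) -> pd.DataFrame:
    """Ward-year counts drawn from the disease-mapping model itself."""
    rng = np.random.default_rng(seed)
    u0 = rng.normal(0, np.sqrt(sigma2_ward), n_wards)
    u1 = (rng.normal(0, np.sqrt(sigma2_slope), n_wards)
          if sigma2_slope > 0 else np.zeros(n_wards))
    rows = []
    for j in range(n_wards):
        for t in range(n_cohorts):
            E = float(rng.integers(e_low, e_high))
            x_boys = rng.uniform(0.4, 0.6)
            eta = b0 + (b1 + u1[j]) * t + u0[j] + covariate_effect * x_boys
            rows.append(dict(ward_id=j, cohort=2010 + t,
                             y_high=int(rng.poisson(E * np.exp(eta))),
                             n_assessed=E, prop_boys=x_boys,
                             prop_most_deprived=rng.uniform(0.1, 0.4),
                             prop_off_age=rng.uniform(0.02, 0.15),
                             median_score=4.0))
    return pd.DataFrame(rows)
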