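import numpy as np
import pandas as pd
import pytest

from kynpath.synthetic import SyntheticConfig, generate_cohort, generate_expression, generate_metabolome


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(n_patients=20, weeks=(0, 2, 6, 14), seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_metabolome(small_cohort, small_config):
    return generate_metabolome(small_cohort, small_config)


@pytest.fixture(scope="session")
def small_expression(small_cohort, small_config):
    return generate_expression(small_cohort, small_config)


@pytest.fixture()
def toy_matrix() -> pd.DataFrame:
    """10 samples x 5 metabolites with constructed missingness:
    m_full fully observed, m8 has 8/10 observed (kept at the 0.8 boundary),
    m7 has 7/10 (dropped), m5 has 5/10 (dropped), m_all fully observed."""
    rng = np.random.default_rng(42)
    idx = [f"s{i}" for i in range(10)]
    df = pd.DataFrame(
        {
            "m_full": rng.uniform(1, 10, 10),
            "m8": rng.uniform(1, 10, 10),
            "m7": rng.uniform(1, 10, 10),
            "m5": rng.uniform(1, 10, 10),
            "m_all": rng.uniform(1, 10, 10),
        },
        index=idx,
    )
    df.loc[["s0", "s3"], "m8"] = np.nan
    df.loc[["s0", "s3", "s5"], "m7"] = np.nan
    df.loc[["s0", "s1", "s2", "s3", "s4"], "m5"] = np.nan
    return df
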