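import numpy as np
import pandas as pd
import pytest

from canopy_yield import FeatureTable, SceneParams, simulate_feature_table


@pytest.fixture(scope="session")
def default_params() -> SceneParams:
    return SceneParams(seed=0)


@pytest.fixture(scope="session")
def table315() -> FeatureTable:
    """One default synthetic feature table at the trial's sample size."""
    return simulate_feature_table(315, seed=0)


def make_table(X: np.ndarray, y: np.ndarray, family: str = "vi",
               prefix: str = "F") -> FeatureTable:
    """Ad-hoc feature table from raw arrays, all columns in one family."""
    cols = [f"{prefix}{i}" for i in range(X.shape[1])]
    df = pd.DataFrame(X, columns=cols)
    df["yield_t_ha"] = y
    return FeatureTable(df, {c: family for c in cols})
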