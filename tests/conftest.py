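import numpy as np
import pandas as pd
import pytest

from bambusa import simulate_ladder


@pytest.fixture(scope="session")
def ladder12():
    """12-rank ladder, 3 genomes per non-focal stratum, 10 My intervals."""
    return simulate_ladder(k_strata=12)


@pytest.fixture(scope="session")
def small_ages():
    """600 genes spread evenly over ranks 1..12."""
    genes = [f"g{i:04d}" for i in range(600)]
    return pd.Series(np.repeat(np.arange(1, 13), 50), index=genes,
                     name="rank")


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
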