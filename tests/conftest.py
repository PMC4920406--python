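import numpy as np
import pandas as pd
import pytest

from meadowforage import synth


@pytest.fixture
def rng():
    return np.random.default_rng(20130501)


@pytest.fixture
def simple_profiles():
    """Two measured species with easy round-number rewards."""
    return pd.DataFrame(
        {
            "species": ["alpha", "beta"],
            "nectar_per_unit_day_ug": [100.0, 10.0],
            "pollen_per_unit_day_ul": [0.5, 0.05],
            "measured": [True, True],
        }
    )


def make_counts(quadrat_counts, species="alpha", site="s1", treatment="P", rnd=1):
    """Long-format count table for one species over a list of quadrat counts."""
    return pd.DataFrame(
        {
            "site": site,
            "treatment": treatment,
            "round": rnd,
            "quadrat_id": [f"q{i}" for i in range(len(quadrat_counts))],
            "species": species,
            "count": quadrat_counts,
        }
    )


@pytest.fixture
def small_config():
    return synth.GeneratorConfig(seed=42, n_species=12, n_sites=1, quadrats_per_site=8)
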