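import numpy as np
import pandas as pd
import pytest

import occutrends as ot


def make_records(rows):
    """Records table from (species, group, site, date) tuples with clean metadata."""
    return pd.DataFrame(
        [
            {
                "species": sp,
                "group": grp,
                "site": site,
                "date": date,
                "spatial_precision_m": 1000,
                "temporal_precision": "day",
            }
            for sp, grp, site, date in rows
        ]
    )


@pytest.fixture
def bee_visit_records():
    """One visit detecting A, C, D plus reference visits; group 'bees'."""
    return make_records(
        [
            ("A", "bees", "s1", "1995-06-01"),
            ("C", "bees", "s1", "1995-06-01"),
            ("D", "bees", "s1", "1995-06-01"),
            ("A", "bees", "s1", "1995-06-02"),
            ("B", "bees", "s2", "1995-06-01"),
            ("C", "bees", "s2", "1995-06-01"),
        ]
    )


@pytest.fixture(scope="session")
def small_scenario():
    """Small synthetic scenario shared by generator and pipeline tests."""
    cfg = ot.ScenarioConfig(
        n_sites={"high": 15, "low": 15, "none": 15},
        n_species=4,
        first_year=2000,
        last_year=2007,
        seed=7,
    )
    return ot.generate_scenario(cfg)


@pytest.fixture(scope="session")
def tiny_model_data():
    """2 sites, 2 years, 3 visits: small enough to enumerate latent states."""
    return ot.ModelData(
        region=np.array([0, 1]),
        vsite=np.array([0, 0, 1]),
        vyear=np.array([0, 1, 1]),
        vdt=np.array([0, 1, 2]),
        vy=np.array([1, 0, 1]),
        n_years=2,
        region_names=("high", "low"),
    ).validate()
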