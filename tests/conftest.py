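import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import diazoniche as dz

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_config():
    """Shared synthetic-study configuration (full niche signal, no censoring)."""
    return dz.SimulationConfig(seed=11, n_db_records=600, nondetect_fraction=0.0)


@pytest.fixture(scope="session")
def synthetic_db(sim_config):
    return dz.make_global_database(sim_config)


@pytest.fixture(scope="session")
def ucynb_fit(synthetic_db):
    db, _ = synthetic_db
    return dz.fit_gam(db, "UCYN-B")


@pytest.fixture(scope="session")
def env_grid(sim_config):
    return dz.make_env_grids(sim_config)


@pytest.fixture
def bottle():
    """A reference bulk incubation bottle with hand-checkable numbers."""
    return dz.IncubationSample(
        station="S1",
        depth_m=5.0,
        par_level=100.0,
        fraction="bulk",
        a_pn_initial=0.3663,
        a_pn_final=0.3763,
        a_n2=1.41,
        pn_conc_umol_l=0.5,
        pn_mass_ug=30.0,
        duration_d=1.0,
    )
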