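import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from grazeform.simulate import SimulationConfig, make_fixture, simulate_survey
from grazeform.survey import Survey

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_survey():
    survey, truth = make_fixture("tiny")
    return survey


@pytest.fixture(scope="session")
def study_scale():
    """One survey at the default study-scale design (33 sites x 30 quadrats)."""
    return simulate_survey(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def planted_clusters():
    return make_fixture("planted_clusters")


def toy_survey() -> Survey:
    """A tiny hand-written survey with easily checked numbers."""
    obs = pd.DataFrame(
        [
            ("A", "Q1", "alpha", 40.0, 40.0, "lateral", True, "none", False),
            ("A", "Q1", "beta", 20.0, 60.0, "upright", False, "none", True),
            ("A", "Q2", "alpha", 30.0, 80.0, "lateral", True, "long", False),
            ("A", "Q2", "beta", 10.0, 60.0, "geniculate", False, "short", True),
            ("B", "Q1", "beta", 50.0, 50.0, "decumbent", False, "none", True),
            ("B", "Q2", "gamma", 25.0, 100.0, "geniculate-upright", False, "none", True),
        ],
        columns=[
            "site_id", "quadrat_id", "species", "cover_pct", "leaf_table_height_mm",
            "culm_orientation", "stolons", "rhizome", "tufted_base",
        ],
    )
    meta = pd.DataFrame(
        [
            ("A", "Q1", 10.0, True),
            ("A", "Q2", 30.0, False),
            ("B", "Q1", 20.0, True),
            ("B", "Q2", 40.0, True),
        ],
        columns=["site_id", "quadrat_id", "bare_ground_pct", "dung_present"],
    )
    sites = pd.DataFrame(
        [("A", 500.0, 60.0, 10.0, 6.5), ("B", 800.0, 50.0, 15.0, 7.0)],
        columns=["site_id", "map_mm", "sand_pct", "cec", "ph"],
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # < 15 quadrats per site, deliberately
        return Survey(obs, meta, sites).validate()


@pytest.fixture
def toy():
    return toy_survey()
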