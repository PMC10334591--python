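"""Shared fixtures: synthetic cities and pipeline runs reused across tests.

The heavier artifacts (a full pipeline run, the access-driven trained
scorer, the 225-tract city) are session-scoped so each is built once.
"""

from __future__ import annotations

import warnings

import pytest

from foodscape.pipeline_cli import (
    assemble_training_matrix,
    config_for_city_dir,
    run_pipeline,
)
from foodscape.scoring_model import tune_and_train
from foodscape.synthetic_data import CityConfig, generate_city, plant_scenario, write_city

warnings.filterwarnings("ignore", message="X does not have valid feature names")


@pytest.fixture(scope="session")
def city_small():
    """A compact 6x6 city for fast structural tests."""
    return generate_city(CityConfig(seed=0, grid=(6, 6)))


@pytest.fixture(scope="session")
def city_default():
    """The default 10x10 city (the pipeline's reference study conditions)."""
    return generate_city(CityConfig(seed=0))


@pytest.fixture(scope="session")
def pipeline_ctx(tmp_path_factory, city_default):
    """A full pipeline run on the default city with the route pair and
    unhealthy corridor planted; shared by end-to-end and scenario tests."""
    city = plant_scenario(city_default, "unhealthy_corridor")
    city = plant_scenario(city, "equal_eta_route_pair")
    city_dir = tmp_path_factory.mktemp("city")
    run_dir = tmp_path_factory.mktemp("run")
    write_city(city, str(city_dir))
    cfg = config_for_city_dir(str(city_dir), str(run_dir), seed=0)
    manifest = run_pipeline(cfg)
    return {"city": city, "cfg": cfg, "manifest": manifest}


@pytest.fixture(scope="session")
def access_city():
    """A city where time-weighted healthy driving access causally drives the
    labels (slow driving keeps the 20-minute reach local)."""
    return generate_city(
        CityConfig(
            seed=0,
            grid=(12, 12),
            drive_kmh=12.0,
            label_driver="driving_access",
            driving_access_threshold=0.35,
        )
    )


@pytest.fixture(scope="session")
def access_scorer(access_city):
    x, y = assemble_training_matrix(access_city)
    return tune_and_train(x, y, seed=0, budget=12), x, y
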