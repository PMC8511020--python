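import dataclasses

import pytest

from ensogrowth import panel as pn
from ensogrowth import synthetic as syn
from ensogrowth.pipeline import prepare_estimation_table


def make_config(seed=7, **overrides) -> syn.WorldConfig:
    """A small, fast world: 6 countries × 3 admin units, 15 tropical years."""
    cfg = syn.WorldConfig(
        n_years=15,
        start_year=1990,
        n_countries=6,
        admin1_per_country=3,
        pixels_per_admin=2,
        seed=seed,
    )
    cfg = dataclasses.replace(cfg, tele=dataclasses.replace(cfg.tele, n_zero_countries=1))
    for key, value in overrides.items():
        obj = cfg
        parts = key.split("__")
        if len(parts) == 1:
            cfg = dataclasses.replace(cfg, **{key: value})
        else:
            sub = dataclasses.replace(getattr(cfg, parts[0]), **{parts[1]: value})
            cfg = dataclasses.replace(cfg, **{parts[0]: sub})
    return cfg


@pytest.fixture(scope="session")
def small_config():
    return make_config()


@pytest.fixture(scope="session")
def small_world(small_config):
    return syn.simulate_world(small_config, with_grid=True, n_children=8000)


@pytest.fixture(scope="session")
def prepared_table(small_world):
    table, _ = prepare_estimation_table(
        small_world.nino, small_world.tele_truth, small_world.children
    )
    return table


@pytest.fixture(scope="session")
def default_spec():
    return pn.ModelSpec()
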