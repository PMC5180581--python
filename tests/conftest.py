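"""Shared fixtures: small, fast study worlds derived from the default config."""
from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from grnswarm.config import FoodTypeConfig, SimConfig, default_config


def override(cfg: SimConfig, **kw) -> SimConfig:
    """Dotted-key config override helper (e.g. ``override(cfg, **{"grn.decay": .1})``)."""
    for key, value in kw.items():
        if "." in key:
            grp, field = key.split(".")
            cfg = dataclasses.replace(
                cfg, **{grp: dataclasses.replace(getattr(cfg, grp), **{field: value})}
            )
        else:
            cfg = dataclasses.replace(cfg, **{key: value})
    return cfg.validate()


@pytest.fixture(scope="session")
def default_cfg() -> SimConfig:
    return default_config()


@pytest.fixture()
def tiny_cfg(default_cfg) -> SimConfig:
    """A 24x24 world with a downscaled population for fast engine tests."""
    food = [
        FoodTypeConfig(threshold=0.0, energy=100.0, initial=180),
        FoodTypeConfig(threshold=30.0, energy=200.0, initial=70),
        FoodTypeConfig(threshold=60.0, energy=400.0, initial=40),
    ]
    return override(
        default_cfg,
        **{
            "world.size": 24,
            "food.types": food,
            "food.reseed_rate": 0.05,
            "population.initial": 60,
            "extinction_threshold": 10,
            "max_steps": 150,
        },
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
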