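"""Shared fixtures: small worlds for unit tests, the default study world
(40×40 km, one year, 60 monitors) for the end-to-end experiments."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from airstack import pipeline, qc, synth


@pytest.fixture(scope="session")
def tiny_world():
    """16×16 grid, 60 days, 16 monitors — cheap world for unit tests."""
    params = synth.WorldParams(nx=16, ny=16, n_days=60,
                               n_hotspot=6, n_background=10)
    return synth.generate_world(params, seed=11)


@pytest.fixture(scope="session")
def default_world():
    """The default study world: 40×40 grid, 365 days, 60 monitors."""
    return synth.generate_world(synth.WorldParams(), seed=7)


def _qc_daily(world) -> pd.DataFrame:
    obs = synth.sample_monitor_observations(world, synth.ObsParams())
    daily, _ = qc.filter_monitor_coverage(
        obs.assign(n_hours=24),
        min_per_month=9,
        min_days_per_year=min(270, int(0.7 * len(world.dates))),
    )
    return daily


@pytest.fixture(scope="session")
def default_daily(default_world):
    """QC-passed daily observations sampled from the default world."""
    return _qc_daily(default_world)


@pytest.fixture(scope="session")
def default_no2_table(default_world, default_daily):
    """Monitor-day Stage-3 training table for the NO2 model."""
    wide = pipeline._stage1_table(default_daily, default_world.monitors)
    return pipeline.build_training_table(default_world, default_world.monitors,
                                         wide, "NO2")


@pytest.fixture(scope="session")
def default_no2_matrices(default_no2_table):
    X, y, groups, cols = pipeline._training_matrices(default_no2_table)
    return X, y, groups


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
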