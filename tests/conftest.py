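"""Shared fixtures: small synthetic worlds and a hand-built toy series."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from excessnowcast.mmwr import Snapshot, SnapshotSeries
from excessnowcast.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_world():
    """4-jurisdiction default-world dataset used by several modules."""
    return simulate_dataset(SimulationConfig(n_jurisdictions=4, rng_seed=11))


def make_snapshot(date, rows, registry=("Alabama", "Alaska")):
    """rows: (jurisdiction, year, week, deaths-or-None-for-masked)."""
    df = pd.DataFrame(rows, columns=["jurisdiction", "mmwr_year", "mmwr_week", "deaths"])
    df["masked"] = df["deaths"].isna()
    df["deaths"] = df["deaths"].astype(float)
    return Snapshot(date, df, registry=registry)


@pytest.fixture(scope="session")
def toy_series():
    """Two jurisdictions, three snapshots, weeks 40-42 of 2020, one masked
    cell; snapshot dates late enough that only the publication-week rule
    matters for eligibility."""
    w = [(2020, 40), (2020, 41), (2020, 42)]
    snaps = [
        make_snapshot(
            dt.date(2020, 10, 28),  # MMWR week 44
            [("Alabama", *w[0], 60), ("Alabama", *w[1], 40), ("Alabama", *w[2], 20),
             ("Alaska", *w[0], 9), ("Alaska", *w[1], None), ("Alaska", *w[2], 3)],
        ),
        make_snapshot(
            dt.date(2020, 11, 4),
            [("Alabama", *w[0], 75), ("Alabama", *w[1], 60), ("Alabama", *w[2], 45),
             ("Alaska", *w[0], 11), ("Alaska", *w[1], 9), ("Alaska", *w[2], None)],
        ),
        make_snapshot(
            dt.date(2021, 6, 2),  # far out: effectively complete
            [("Alabama", *w[0], 100), ("Alabama", *w[1], 90), ("Alabama", *w[2], 80),
             ("Alaska", *w[0], 14), ("Alaska", *w[1], 12), ("Alaska", *w[2], 11)],
        ),
    ]
    return SnapshotSeries(snaps)
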