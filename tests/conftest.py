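"""Shared fixtures and tiny instance builders."""

from __future__ import annotations

import pandas as pd
import pytest

from rangeconnect import SynthConfig, build_network, simulate


def chain_table(areas, basin="b0", prefix="u"):
    """Chain network table: u0 is the outlet, u_{k} drains into u_{k-1}."""
    rows = []
    for i, a in enumerate(areas):
        rows.append({
            "id": f"{prefix}{i}",
            "area": float(a),
            "next_down": None if i == 0 else f"{prefix}{i - 1}",
            "main_basin": basin,
            "coarse_parent": f"c_{basin}",
        })
    return pd.DataFrame(rows)


def chain_network(areas, basin="b0", prefix="u"):
    return build_network(chain_table(areas, basin=basin, prefix=prefix))


def small_world(seed, n_units=120, n_basins=4, n_species=20,
                n_dams_existing=8, n_dams_future=4, **kw):
    """A small synthetic instance for oracle comparisons."""
    cfg = SynthConfig(
        seed=seed, n_units=n_units, n_basins=n_basins, n_species=n_species,
        n_dams_existing=n_dams_existing, n_dams_future=n_dams_future,
        range_size_mean=kw.pop("range_size_mean", 12.0), **kw,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def world():
    """One medium synthetic world shared across read-only tests."""
    return small_world(seed=7, n_units=300, n_basins=6, n_species=40,
                       n_dams_existing=15, n_dams_future=6)


@pytest.fixture()
def chain4():
    """4-unit chain with unit areas, outlet first."""
    return chain_network([1.0, 1.0, 1.0, 1.0])
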