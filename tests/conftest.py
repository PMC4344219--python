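"""Shared fixtures: the published worked-example tract table and small
synthetic surveys."""

from __future__ import annotations

import pandas as pd
import pytest

from cvregion import build_contiguity, synth
from cvregion.survey import AreaTable, VariableSpec

# Five poverty-scenario attributes for four adjacent Chicago tracts, as
# published (percent estimates with percent MOEs).
TRACT_IDS = ["222600", "222700", "222800", "222900"]
TRACT_CELLS = {
    "owner_cost": {"est": [28.9, 28.4, 63.3, 46.5], "moe": [15.7, 10.2, 114.5, 19.7]},
    "renter_cost": {"est": [32.0, 38.8, 39.2, 48.3], "moe": [9.1, 15.4, 15.6, 23.1]},
    "child_above_pov": {"est": [89.7, 53.0, 33.7, 59.2], "moe": [19.5, 26.8, 29.9, 18.2]},
    "total_above_pov": {"est": [78.7, 74.7, 61.9, 64.6], "moe": [10.2, 7.5, 21.0, 14.8]},
    "employed": {"est": [94.9, 78.5, 88.9, 87.7], "moe": [3.6, 8.5, 6.2, 31.0]},
}


@pytest.fixture(scope="session")
def tract_specs() -> list[VariableSpec]:
    # directly published percentages: read as single estimate/MOE pairs
    return [
        VariableSpec(name, "count", num_est=f"{name}_est", num_moe=f"{name}_moe")
        for name in TRACT_CELLS
    ]


@pytest.fixture(scope="session")
def tract_table(tract_specs) -> AreaTable:
    data: dict = {"households": [1500] * 4, "pop_est": [4000.0] * 4, "pop_moe": [300.0] * 4}
    for name, cells in TRACT_CELLS.items():
        data[f"{name}_est"] = cells["est"]
        data[f"{name}_moe"] = cells["moe"]
    df = pd.DataFrame(data, index=pd.Index(TRACT_IDS, name="area_id"))
    return AreaTable(df)


@pytest.fixture(scope="session")
def tract_csv(tmp_path_factory, tract_table) -> str:
    path = tmp_path_factory.mktemp("tracts") / "tracts.csv"
    tract_table.df.to_csv(path)
    return str(path)


@pytest.fixture(scope="session")
def small_survey() -> synth.SyntheticSurvey:
    """6x6 lattice, quadrant zones, realistic sample sizes."""
    return synth.generate(6, 6, seed=7)


@pytest.fixture(scope="session")
def small_graph(small_survey):
    return build_contiguity(small_survey.geometries)
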