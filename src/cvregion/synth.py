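"""Synthetic lattice surveys with known ground truth.

Generates a rectangular lattice of unit-square "tracts" partitioned into
planted homogeneous zones.  Each area gets a sample size (completed surveys,
Poisson around ``mean_sample`` — the real-world anchor is roughly 135
completed surveys per tract over a 5-year pooled period), and every
published cell is

    estimate = truth + Normal(0, sd_unit / sqrt(sample size)),
    MOE      = 1.645 * sd_unit / sqrt(sample size),

so margins of error are consistent with the sampling noise by construction
and nominal 90% interval coverage holds exactly.  Proportion variables are
emitted as numerator/denominator count pairs (denominator = population) so
the full derived-ratio error propagation path is exercised; per-respondent
sds are binomial (sqrt(p(1-p)) per person) for numerators and half the
population for the population count, giving tract-population CVs of a few
percent at realistic sample sizes.

Zone means for each variable are separated by ``effect`` within-zone
standard deviations between adjacent levels, with the level-to-zone mapping
drawn at random per variable, so different variables disagree about which
zones are "high" — the multivariate structure the objective must balance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import box

from .errors import ConfigError
from .survey import AreaTable, Partition, VariableSpec
from .uncertainty import Z90, UncertainValue, derived_se

#: within-zone standard deviation of true proportions (proportion points)
WITHIN_ZONE_SD = 0.04
#: per-person sd of the population count relative to the population
POP_UNIT_SD = 0.5


@dataclass
class SyntheticSurvey:
    table: AreaTable
    geometries: list[tuple[str, object]]
    specs: list[VariableSpec]
    truth: pd.DataFrame
    rows: int
    cols: int
    seed: int


def _zone_labels(rows: int, cols: int, zones) -> np.ndarray:
    """Zone layout: 'quadrants', 'bands:K', or an explicit (rows, cols) array."""
    if isinstance(zones, str):
        if zones == "quadrants":
            lab = np.zeros((rows, cols), dtype=int)
            lab[rows // 2 :, :] += 2
            lab[:, cols // 2 :] += 1
            return lab
        if zones.startswith("bands:"):
            k = int(zones.split(":", 1)[1])
            if k < 1 or k > rows:
                raise ConfigError(f"cannot tile {rows} rows into {k} bands")
            edges = np.linspace(0, rows, k + 1).round().astype(int)
            lab = np.zeros((rows, cols), dtype=int)
            for z in range(k):
                lab[edges[z] : edges[z + 1], :] = z
            return lab
        raise ConfigError(f"unknown zone layout {zones!r}")
    lab = np.asarray(zones, dtype=int)
    if lab.shape != (rows, cols):
        raise ConfigError(f"zone array shape {lab.shape} does not tile {rows}x{cols}")
    return lab


def _area_id(r: int, c: int) -> str:
    return f"a{r:02d}{c:02d}"


def generate(
    rows: int,
    cols: int,
    zones="quadrants",
    effect: float = 3.0,
    mean_sample: float = 135.0,
    seed: int = 0,
    n_proportions: int = 5,
    n_counts: int = 1,
) -> SyntheticSurvey:
    """Generate a lattice survey with planted zones.

    *effect* is the separation of adjacent zone means in units of the
    within-zone sd; 0 plants no signal.  Sample sizes are Poisson around
    *mean_sample* with a floor of 10 completed surveys.
    """
    if rows * cols < 4:
        raise ConfigError("lattice must have at least 4 areas")
    if n_proportions < 1:
        raise ConfigError("need at least one proportion variable")
    rng = np.random.default_rng(seed)
    lab = _zone_labels(rows, cols, zones)
    n_zones = int(lab.max()) + 1
    n = rows * cols
    zone = lab.reshape(-1)

    samples = np.maximum(10, rng.poisson(mean_sample, size=n)).astype(float)
    true_pop = np.clip(rng.normal(4000.0, 400.0, size=n), 500.0, None)

    pop_se = POP_UNIT_SD * true_pop / np.sqrt(samples)
    pop_est = np.clip(true_pop + rng.normal(0.0, 1.0, size=n) * pop_se, 1.0, None)

    data: dict[str, np.ndarray] = {
        "households": np.maximum(1, np.round(true_pop / 2.5)).astype(int),
        "pop_est": pop_est,
        "pop_moe": Z90 * pop_se,
    }
    truth: dict[str, np.ndarray] = {
        "zone": zone,
        "sample_size": samples.astype(int),
        "true_pop": true_pop,
    }
    specs: list[VariableSpec] = []

    # centered zone levels, permuted per variable
    base_levels = (np.arange(n_zones) - (n_zones - 1) / 2) * effect * WITHIN_ZONE_SD

    for d in range(n_proportions):
        name = f"prop{d + 1}"
        base_p = 0.5 if n_proportions == 1 else 0.25 + 0.5 * d / (n_proportions - 1)
        levels = base_levels[rng.permutation(n_zones)]
        zone_mean = np.clip(base_p + levels, 0.06, 0.94)
        p_true = np.clip(zone_mean[zone] + rng.normal(0.0, WITHIN_ZONE_SD, size=n), 0.02, 0.98)
        num_true = p_true * true_pop
        num_se = true_pop * np.sqrt(p_true * (1 - p_true)) / np.sqrt(samples)
        num_est = np.clip(num_true + rng.normal(0.0, 1.0, size=n) * num_se, 0.0, pop_est)
        data[f"{name}_est"] = num_est
        data[f"{name}_moe"] = Z90 * num_se
        truth[f"{name}_true"] = p_true
        specs.append(
            VariableSpec(
                name,
                "proportion",
                num_est=f"{name}_est",
                num_moe=f"{name}_moe",
                den_est="pop_est",
                den_moe="pop_moe",
            )
        )

    for d in range(n_counts):
        name = f"count{d + 1}"
        levels = base_levels[rng.permutation(n_zones)] * 0.3
        zone_rate = np.clip(0.10 + levels, 0.02, 0.5)
        rate = np.clip(zone_rate[zone] + rng.normal(0.0, 0.3 * WITHIN_ZONE_SD, size=n), 0.01, 0.6)
        c_true = rate * true_pop
        c_se = true_pop * np.sqrt(rate * (1 - rate)) / np.sqrt(samples)
        c_est = np.clip(c_true + rng.normal(0.0, 1.0, size=n) * c_se, 0.0, None)
        data[f"{name}_est"] = c_est
        data[f"{name}_moe"] = Z90 * c_se
        truth[f"{name}_true"] = c_true
        specs.append(VariableSpec(name, "count", num_est=f"{name}_est", num_moe=f"{name}_moe"))

    ids = [_area_id(r, c) for r in range(rows) for c in range(cols)]
    df = pd.DataFrame(data, index=pd.Index(ids, name="area_id"))
    truth_df = pd.DataFrame(truth, index=pd.Index(ids, name="area_id"))
    geoms = [
        (_area_id(r, c), box(c, rows - 1 - r, c + 1, rows - r))
        for r in range(rows)
        for c in range(cols)
    ]
    table = AreaTable(df)
    return SyntheticSurvey(table, geoms, specs, truth_df, rows, cols, seed)


def degrade(survey: SyntheticSurvey, areas: Sequence[str], factor: float) -> SyntheticSurvey:
    """Multiply listed areas' MOEs by *factor* (> 1), rescaling sample sizes.

    A factor-f inflation of every SE corresponds to f^2 fewer completed
    surveys.  Used to test that only poor-quality areas are forced to merge.
    """
    if factor <= 1:
        raise ConfigError("degradation factor must exceed 1")
    df = survey.table.df.copy()
    truth = survey.truth.copy()
    moe_cols = [c for c in df.columns if c.endswith("_moe")]
    idx = list(areas)
    df.loc[idx, moe_cols] = df.loc[idx, moe_cols] * factor
    truth.loc[idx, "sample_size"] = np.maximum(
        1, (truth.loc[idx, "sample_size"] / factor**2).round()
    ).astype(int)
    return replace(survey, table=AreaTable(df), truth=truth)


def area_cv_table(table: AreaTable, specs: Sequence[VariableSpec]) -> pd.DataFrame:
    """Per-area CV for every variable (derived variables via error propagation)."""
    out = {}
    for spec in specs:
        cvs = np.empty(table.n_areas)
        for i, area in enumerate(table.df.index):
            num = UncertainValue.from_moe(
                float(table.df.at[area, spec.num_est]),
                float(table.df.at[area, spec.num_moe]),
            )
            if spec.kind == "count":
                val = num
            else:
                den = UncertainValue.from_moe(
                    float(table.df.at[area, spec.den_est]),
                    float(table.df.at[area, spec.den_moe]),
                )
                val = derived_se(num, den, spec.kind)
            if val.estimate > 0:
                cvs[i] = val.se / val.estimate
            else:
                cvs[i] = 0.0 if val.se == 0 else math.inf
        out[spec.name] = cvs
    return pd.DataFrame(out, index=table.df.index)


def binding_cv(table: AreaTable, specs: Sequence[VariableSpec]) -> pd.Series:
    """Each area's worst constraint-relevant CV.

    The maximum CV over variables, ignoring proportions whose estimate falls
    under the 5% exemption threshold (their CV constraint would be waived).
    """
    from .preprocess import PROPORTION_EXEMPTION_THRESHOLD

    cvs = area_cv_table(table, specs)
    binding = np.zeros(table.n_areas)
    for spec in specs:
        col = cvs[spec.name].to_numpy()
        if spec.kind == "proportion":
            est = (
                table.df[spec.num_est].to_numpy(float)
                / table.df[spec.den_est].to_numpy(float)
            )
            col = np.where(est < PROPORTION_EXEMPTION_THRESHOLD, 0.0, col)
        binding = np.maximum(binding, col)
    return pd.Series(binding, index=table.df.index)


def cv_target_for_region_size(
    table: AreaTable, specs: Sequence[VariableSpec], target_size: float
) -> float:
    """A CV target that forces regions of roughly *target_size* areas.

    For count-like sampling, aggregating m comparable areas shrinks the CV by
    about sqrt(m), so a target of (median binding area CV) / sqrt(m) makes
    the median area need about m partners.
    """
    return float(binding_cv(table, specs).median()) / math.sqrt(target_size)


def zone_purity(partition: Partition, truth: pd.DataFrame) -> float:
    """Boundary-agreement score: the share of areas whose region's majority
    planted zone matches their own zone.  1.0 means every region boundary
    lies on a planted-zone boundary."""
    zone = truth["zone"]
    correct = 0
    for members in partition.regions.values():
        zones = zone.loc[sorted(members)]
        correct += int((zones == zones.mode().iloc[0]).sum())
    return correct / len(partition.assignment)


def write_survey(survey: SyntheticSurvey, out_dir: str | Path) -> dict[str, Path]:
    """Write the survey in the exact formats the readers consume."""
    from shapely.geometry import mapping as geom_mapping

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["table"] = out_dir / "areas.csv"
    survey.table.df.to_csv(paths["table"], float_format="%.12g")

    features = [
        {
            "type": "Feature",
            "properties": {"area_id": aid},
            "geometry": geom_mapping(geom),
        }
        for aid, geom in survey.geometries
    ]
    paths["geojson"] = out_dir / "areas.geojson"
    with open(paths["geojson"], "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)

    paths["truth"] = out_dir / "truth.csv"
    survey.truth.to_csv(paths["truth"], float_format="%.12g")

    paths["variables"] = out_dir / "variables.json"
    with open(paths["variables"], "w") as fh:
        json.dump(
            {
                "variables": {
                    s.name: {
                        "kind": s.kind,
                        "num_est": s.num_est,
                        "num_moe": s.num_moe,
                        **(
                            {"den_est": s.den_est, "den_moe": s.den_moe}
                            if s.den_est
                            else {}
                        ),
                    }
                    for s in survey.specs
                }
            },
            fh,
            indent=2,
        )
    return paths
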