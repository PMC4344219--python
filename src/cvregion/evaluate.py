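"""Information-loss diagnostics for a regionalization solution.

The central diagnostic asks, for each area and variable, whether the
region-level estimate falls inside the area's own margin of error.  The
share of areas for which it does is S_j (per variable); their unweighted
mean is the overall score S.  Counts are excluded: a region-level count is
by construction larger than any member area's count, so the comparison is
meaningless for them.  A per-(area, variable) diagnostic table backs scatter
plots of area vs region estimates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .survey import AreaTable, Partition, VariableSpec
from .uncertainty import UncertainValue, aggregate_count, cv, derived_se


@dataclass
class EvalReport:
    s_j: dict[str, float]
    s: float
    areas_per_region: float
    n_regions: int
    n_areas: int
    diagnostics: pd.DataFrame = field(repr=False, default=None)


def _area_values(table: AreaTable, spec: VariableSpec) -> tuple[np.ndarray, np.ndarray]:
    """Area-level (estimate, moe) for one variable, derived when needed."""
    if spec.kind == "count":
        est = table.df[spec.num_est].to_numpy(float)
        moe = table.df[spec.num_moe].to_numpy(float)
        return est, moe
    est = np.empty(table.n_areas)
    moe = np.empty(table.n_areas)
    for i, area in enumerate(table.df.index):
        num = UncertainValue.from_moe(
            float(table.df.at[area, spec.num_est]), float(table.df.at[area, spec.num_moe])
        )
        den = UncertainValue.from_moe(
            float(table.df.at[area, spec.den_est]), float(table.df.at[area, spec.den_moe])
        )
        val = derived_se(num, den, spec.kind)
        est[i] = val.estimate
        moe[i] = val.moe
    return est, moe


def _region_values(
    partition: Partition, table: AreaTable, spec: VariableSpec
) -> dict[int, float]:
    """Region-level attribute value: aggregated count or re-derived ratio."""
    out = {}
    for label, members in partition.regions.items():
        members = sorted(members)
        nums = [
            UncertainValue.from_moe(
                float(table.df.at[a, spec.num_est]), float(table.df.at[a, spec.num_moe])
            )
            for a in members
        ]
        agg_num = aggregate_count(nums)
        if spec.kind == "count":
            out[label] = agg_num.estimate
        else:
            dens = [
                UncertainValue.from_moe(
                    float(table.df.at[a, spec.den_est]), float(table.df.at[a, spec.den_moe])
                )
                for a in members
            ]
            agg_den = aggregate_count(dens)
            out[label] = agg_num.estimate / agg_den.estimate if agg_den.estimate > 0 else math.nan
    return out


def s_j(
    partition: Partition,
    table: AreaTable,
    specs: Sequence[VariableSpec],
    variable: str,
) -> float:
    """Share of areas whose region estimate lies within the area's own MOE.

    Defined for proportion and mean variables only.  An exactly zero
    difference counts as within even when the MOE is zero (a singleton region
    loses no information regardless of its MOE).
    """
    spec = _find(specs, variable)
    if spec.kind == "count":
        raise ConfigError(
            f"S_j is undefined for count variable {variable!r}: a region count "
            "always exceeds its member areas' counts"
        )
    est, moe = _area_values(table, spec)
    region_val = _region_values(partition, table, spec)
    ids = list(table.df.index)
    within = 0
    for i, area in enumerate(ids):
        rv = region_val[partition.assignment[area]]
        diff = abs(est[i] - rv)
        if diff == 0 or diff < moe[i]:
            within += 1
    return within / len(ids)


def _find(specs: Sequence[VariableSpec], name: str) -> VariableSpec:
    for spec in specs:
        if spec.name == name:
            return spec
    raise ConfigError(f"unknown variable {name!r}")


def s_global(s_values: Sequence[float]) -> float:
    """Unweighted mean of per-variable S_j scores."""
    if not s_values:
        raise ValueError("need at least one evaluated variable")
    return float(np.mean(s_values))


def areas_per_region(partition: Partition) -> float:
    """Average number of areas per region."""
    return len(partition.assignment) / partition.n_regions


def diagnostic_table(
    partition: Partition,
    table: AreaTable,
    specs: Sequence[VariableSpec],
    cv_threshold: float,
) -> pd.DataFrame:
    """One record per (area, evaluated variable) for diagnostic plots.

    Columns: area estimate and MOE, region estimate, whether the area met the
    CV threshold on its own (``cv_pass``), and whether the region estimate
    lies within the area's MOE (``within_moe``).  The per-variable mean of
    ``within_moe`` equals S_j.
    """
    records = []
    ids = list(table.df.index)
    for spec in specs:
        if spec.kind == "count":
            continue
        est, moe = _area_values(table, spec)
        region_val = _region_values(partition, table, spec)
        for i, area in enumerate(ids):
            rv = region_val[partition.assignment[area]]
            diff = abs(est[i] - rv)
            records.append(
                {
                    "area_id": area,
                    "variable": spec.name,
                    "region": partition.assignment[area],
                    "area_est": est[i],
                    "area_moe": moe[i],
                    "region_est": rv,
                    "cv_pass": cv(est[i], moe[i]) <= cv_threshold,
                    "within_moe": bool(diff == 0 or diff < moe[i]),
                }
            )
    return pd.DataFrame.from_records(records)


def evaluate_partition(
    partition: Partition,
    table: AreaTable,
    specs: Sequence[VariableSpec],
    cv_threshold: float,
) -> EvalReport:
    """Full evaluation: S_j per proportion/mean variable, S, region sizes."""
    evaluated = [s for s in specs if s.kind != "count"]
    if not evaluated:
        raise ConfigError("no proportion or mean variables to evaluate")
    sj = {spec.name: s_j(partition, table, specs, spec.name) for spec in evaluated}
    diag = diagnostic_table(partition, table, specs, cv_threshold)
    return EvalReport(
        s_j=sj,
        s=s_global(list(sj.values())),
        areas_per_region=areas_per_region(partition),
        n_regions=partition.n_regions,
        n_areas=len(partition.assignment),
        diagnostics=diag,
    )


def write_report(report: EvalReport, out_dir: str | Path) -> dict[str, Path]:
    """Write the JSON summary and the delimited diagnostic table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    summary = {
        "s": report.s,
        "s_j": report.s_j,
        "areas_per_region": report.areas_per_region,
        "n_regions": report.n_regions,
        "n_areas": report.n_areas,
    }
    paths["summary"] = out_dir / "evaluation.json"
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=2)
    paths["diagnostics"] = out_dir / "diagnostics.csv"
    report.diagnostics.to_csv(paths["diagnostics"], index=False)
    return paths
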