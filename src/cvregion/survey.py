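"""Survey data model, file readers/writers, and contiguity graphs.

An :class:`AreaTable` holds one row per small area (census tract, block
group, ...) with a households count, a population estimate + MOE, and per
variable estimate/MOE columns.  Variables are declared with
:class:`VariableSpec`: a ``count`` variable is a single estimate/MOE column
pair, while a ``proportion`` or ``mean`` is derived from numerator and
denominator count pairs so that region-level values can be re-aggregated with
proper error propagation.

Spatial adjacency lives in a :class:`ContiguityGraph` built either from
polygon geometries (queen contiguity by default: any shared boundary point;
rook: a shared boundary segment) or from an explicit whitespace-delimited
adjacency-list file.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import networkx as nx
import pandas as pd
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .errors import ConfigError, DataError
from .uncertainty import Z90, region_cv_table

VariableKind = Literal["count", "proportion", "mean"]


@dataclass(frozen=True)
class VariableSpec:
    """Declaration of one survey variable.

    ``count`` variables reference a single estimate/MOE column pair
    (``num_est``/``num_moe``); ``proportion`` and ``mean`` variables
    additionally reference denominator columns.  ``cv_target`` overrides the
    global CV target for this variable when present.
    """

    name: str
    kind: VariableKind
    num_est: str
    num_moe: str
    den_est: str | None = None
    den_moe: str | None = None
    cv_target: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("count", "proportion", "mean"):
            raise ConfigError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        if self.kind in ("proportion", "mean") and (self.den_est is None or self.den_moe is None):
            raise ConfigError(
                f"variable {self.name!r}: kind {self.kind!r} requires denominator columns"
            )
        if self.cv_target is not None and self.cv_target <= 0:
            raise ConfigError(f"variable {self.name!r}: cv_target must be positive")

    @property
    def columns(self) -> list[str]:
        cols = [self.num_est, self.num_moe]
        if self.den_est is not None:
            cols += [self.den_est, self.den_moe]
        return cols


@dataclass(frozen=True)
class Constraints:
    """Feasibility constraints for output regions.

    At least one CV target must be defined (globally or per variable);
    population bounds are optional and apply to the summed population
    estimate of a region.
    """

    global_cv: float | None = None
    population_min: float | None = None
    population_max: float | None = None

    def __post_init__(self) -> None:
        if self.global_cv is not None and self.global_cv <= 0:
            raise ConfigError("global_cv must be positive")
        for bound in (self.population_min, self.population_max):
            if bound is not None and bound < 0:
                raise ConfigError("population bounds must be nonnegative")
        if (
            self.population_min is not None
            and self.population_max is not None
            and self.population_min > self.population_max
        ):
            raise ConfigError("population_min exceeds population_max")

    def cv_target(self, spec: VariableSpec) -> float:
        target = spec.cv_target if spec.cv_target is not None else self.global_cv
        if target is None:
            raise ConfigError(
                f"no CV target for variable {spec.name!r} and no global target set"
            )
        return target

    def validate(self, specs: Sequence[VariableSpec]) -> None:
        for spec in specs:
            self.cv_target(spec)


@dataclass
class AreaTable:
    """Per-area estimates and margins of error, indexed by area id."""

    df: pd.DataFrame
    households_col: str = "households"
    pop_est_col: str = "pop_est"
    pop_moe_col: str = "pop_moe"

    @property
    def area_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def n_areas(self) -> int:
        return len(self.df)

    def households(self, area: str) -> float:
        return float(self.df.at[area, self.households_col])

    def population(self, area: str) -> float:
        return float(self.df.at[area, self.pop_est_col])

    def subset(self, ids: Iterable[str]) -> "AreaTable":
        return AreaTable(
            self.df.loc[list(ids)].copy(),
            self.households_col,
            self.pop_est_col,
            self.pop_moe_col,
        )


def _require_columns(df: pd.DataFrame, columns: Iterable[str]) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ConfigError(f"missing column(s) in area table: {', '.join(missing)}")


def read_area_table(
    path: str | Path,
    specs: Sequence[VariableSpec],
    *,
    id_col: str = "area_id",
    households_col: str = "households",
    pop_est_col: str = "pop_est",
    pop_moe_col: str = "pop_moe",
) -> AreaTable:
    """Read a comma-delimited area table with strict numeric parsing.

    Every column referenced by *specs* plus the households and population
    columns must be present.  Non-numeric cells raise a :class:`DataError`
    naming the offending area; MOEs are kept verbatim (preprocessing rules
    are applied later, explicitly).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str})
    if df.empty:
        raise DataError(f"{path}: no data rows")
    needed = [households_col, pop_est_col, pop_moe_col]
    for spec in specs:
        needed += spec.columns
    _require_columns(df, [id_col] + needed)
    df[id_col] = df[id_col].astype(str)
    if df[id_col].duplicated().any():
        dups = df.loc[df[id_col].duplicated(), id_col].tolist()
        raise DataError(f"duplicate area id(s): {', '.join(dups)}")
    df = df.set_index(id_col)
    for col in dict.fromkeys(needed):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if df[col].isna().any():
            bad |= df[col].isna()
        if bad.any():
            area = bad.idxmax()
            raise DataError(f"non-numeric or missing value in column {col!r}, area {area!r}")
        df[col] = parsed.astype(float)
    for spec in specs:
        moes = [spec.num_moe] + ([spec.den_moe] if spec.den_moe else [])
        for col in moes:
            if (df[col] < 0).any():
                area = df.index[(df[col] < 0)][0]
                raise DataError(f"negative MOE in column {col!r}, area {area!r}")
    if (df[households_col] < 0).any():
        raise DataError("negative households count")
    return AreaTable(df, households_col, pop_est_col, pop_moe_col)


class ContiguityGraph:
    """Symmetric adjacency among areas (no self-loops), backed by networkx."""

    def __init__(self, nodes: Iterable[str], edges: Iterable[tuple[str, str]] = ()) -> None:
        self.g = nx.Graph()
        self.g.add_nodes_from(nodes)
        for a, b in edges:
            if a == b:
                raise DataError(f"self-loop on area {a!r}")
            self.g.add_edge(a, b)

    @property
    def nodes(self) -> set[str]:
        return set(self.g.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.g.edges}

    def neighbors(self, area: str) -> set[str]:
        return set(self.g.neighbors(area))

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.g)]

    def is_connected_subset(self, areas: Iterable[str]) -> bool:
        areas = set(areas)
        if not areas:
            return False
        return nx.is_connected(self.g.subgraph(areas))

    def restrict(self, areas: Iterable[str]) -> "ContiguityGraph":
        keep = set(areas)
        unknown = keep - self.nodes
        if unknown:
            raise DataError(f"unknown area id(s): {', '.join(sorted(unknown))}")
        out = ContiguityGraph(keep)
        out.g.add_edges_from(e for e in self.g.edges if e[0] in keep and e[1] in keep)
        return out


def read_geojson(path: str | Path) -> list[tuple[str, BaseGeometry]]:
    """Read a GeoJSON FeatureCollection with an ``area_id`` property."""
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise DataError(f"{path}: expected a GeoJSON FeatureCollection")
    out = []
    for feat in doc.get("features", []):
        props = feat.get("properties") or {}
        if "area_id" not in props:
            raise DataError(f"{path}: feature without an 'area_id' property")
        out.append((str(props["area_id"]), geom_shape(feat["geometry"])))
    return out


def build_contiguity(
    geometries: Sequence[tuple[str, BaseGeometry]] | Mapping[str, BaseGeometry],
    rule: Literal["queen", "rook"] = "queen",
) -> ContiguityGraph:
    """Build a contiguity graph from polygons.

    Queen contiguity (default) connects areas sharing any boundary point,
    including a single corner; rook requires a shared boundary segment of
    positive length.
    """
    if isinstance(geometries, Mapping):
        items = list(geometries.items())
    else:
        items = list(geometries)
    ids = [i for i, _ in items]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise DataError(f"duplicate area id in geometries: {i!r}")
        seen.add(i)
    for i, geom in items:
        if geom.is_empty or not geom.is_valid:
            raise DataError(f"invalid or empty geometry for area {i!r}")
    graph = ContiguityGraph(ids)
    geoms = [g for _, g in items]
    tree = STRtree(geoms)
    for idx, geom in enumerate(geoms):
        for jdx in tree.query(geom, predicate="intersects"):
            jdx = int(jdx)
            if jdx <= idx:
                continue
            inter = geom.intersection(geoms[jdx])
            if inter.is_empty:
                continue
            if rule == "rook" and inter.length == 0:
                continue
            graph.g.add_edge(ids[idx], ids[jdx])
    return graph


def read_adjacency(path: str | Path, nodes: Iterable[str]) -> ContiguityGraph:
    """Read a whitespace-delimited adjacency list (one ``id id`` pair per line).

    The edge set is symmetrized; ids must belong to *nodes* and self-pairs are
    rejected.
    """
    nodes = list(nodes)
    known = set(nodes)
    graph = ContiguityGraph(nodes)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise DataError(f"{path}:{lineno}: expected two ids, got {line!r}")
            a, b = parts
            if a not in known or b not in known:
                bad = a if a not in known else b
                raise DataError(f"{path}:{lineno}: unknown area id {bad!r}")
            if a == b:
                raise DataError(f"{path}:{lineno}: self-pair {a!r}")
            graph.g.add_edge(a, b)
    return graph


def repair_islands(
    graph: ContiguityGraph,
    add_links: Sequence[tuple[str, str]] = (),
    drop_areas: Sequence[str] = (),
) -> tuple[ContiguityGraph, dict]:
    """Apply manual island fixes: bridge links and outright exclusions.

    Islands (disconnected components) either get an artificial link to the
    mainland — e.g. where a bridge exists — or are excluded entirely when too
    small or too distinct to regionalize.  Returns the repaired graph and a
    report with the dropped areas and remaining components.
    """
    dropped = set(drop_areas)
    unknown = dropped - graph.nodes
    if unknown:
        raise DataError(f"drop_areas references unknown id(s): {', '.join(sorted(unknown))}")
    for a, b in add_links:
        if a in dropped or b in dropped:
            raise DataError(f"link ({a!r}, {b!r}) references a dropped area")
        if a not in graph.nodes or b not in graph.nodes:
            bad = a if a not in graph.nodes else b
            raise DataError(f"link references unknown area id {bad!r}")
        if a == b:
            raise DataError(f"link is a self-pair: {a!r}")
    out = ContiguityGraph(graph.nodes - dropped)
    out.g.add_edges_from(
        e for e in graph.g.edges if e[0] not in dropped and e[1] not in dropped
    )
    out.g.add_edges_from(add_links)
    report = {
        "dropped": sorted(dropped),
        "links_added": [tuple(l) for l in add_links],
        "components": [sorted(c) for c in out.components()],
    }
    return out, report


@dataclass
class Partition:
    """An exhaustive, exclusive assignment of areas to contiguous regions."""

    assignment: dict[str, int]
    regions: dict[int, set[str]] = field(default_factory=dict)
    region_table: pd.DataFrame | None = None
    ssd: float = math.nan
    n_regions: int = 0

    def __post_init__(self) -> None:
        if not self.regions:
            self.regions = {}
            for area, label in self.assignment.items():
                self.regions.setdefault(label, set()).add(area)
        self.n_regions = len(self.regions)

    @classmethod
    def from_assignment(
        cls,
        assignment: Mapping[str, int],
        graph: ContiguityGraph | None = None,
        table: AreaTable | None = None,
        specs: Sequence[VariableSpec] | None = None,
    ) -> "Partition":
        part = cls(dict(assignment))
        if graph is not None:
            missing = graph.nodes - set(assignment)
            if missing:
                raise DataError(
                    f"assignment missing area(s): {', '.join(sorted(missing))}"
                )
            for label, members in part.regions.items():
                if not graph.is_connected_subset(members):
                    raise DataError(f"region {label} is not contiguous")
        if table is not None and specs is not None:
            part.region_table = compute_region_table(part, table, specs)
        return part

    def relabel_dense(self, order: Sequence[int] | None = None) -> "Partition":
        """Relabel regions with dense integers 0..p-1 (cosmetic)."""
        labels = list(order) if order is not None else sorted(self.regions)
        remap = {old: new for new, old in enumerate(labels)}
        return Partition({a: remap[l] for a, l in self.assignment.items()})


def compute_region_table(
    partition: Partition, table: AreaTable, specs: Sequence[VariableSpec]
) -> pd.DataFrame:
    """Per-region estimates, MOEs and CVs for every declared variable."""
    rows = []
    for label in sorted(partition.regions):
        members = sorted(partition.regions[label])
        stats = region_cv_table(members, table, specs)
        pop = sum(table.population(a) for a in members)
        row: dict[str, object] = {
            "region": label,
            "n_areas": len(members),
            "population": pop,
        }
        for spec in specs:
            est, se, cval = stats[spec.name]
            row[f"{spec.name}_est"] = est
            row[f"{spec.name}_moe"] = se * Z90
            row[f"{spec.name}_cv"] = cval
        rows.append(row)
    return pd.DataFrame(rows).set_index("region")


def write_partition(
    partition: Partition,
    out_dir: str | Path,
    table: AreaTable,
    specs: Sequence[VariableSpec],
    geometries: Sequence[tuple[str, BaseGeometry]] | None = None,
) -> dict[str, Path]:
    """Write assignment and region tables (CSV) and optional dissolved GeoJSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    assign = pd.DataFrame(
        {"area_id": list(partition.assignment), "region": list(partition.assignment.values())}
    ).sort_values("area_id")
    paths["assignment"] = out_dir / "assignment.csv"
    assign.to_csv(paths["assignment"], index=False)

    region_table = partition.region_table
    if region_table is None:
        region_table = compute_region_table(partition, table, specs)
    paths["regions"] = out_dir / "regions.csv"
    region_table.to_csv(paths["regions"], float_format="%.12g")

    if geometries is not None:
        lookup = dict(geometries)
        features = []
        for label in sorted(partition.regions):
            geoms = [lookup[a] for a in partition.regions[label] if a in lookup]
            if not geoms:
                continue
            merged = unary_union(geoms)
            features.append(
                {
                    "type": "Feature",
                    "properties": {"region": int(label)},
                    "geometry": geom_mapping(merged),
                }
            )
        paths["geojson"] = out_dir / "regions.geojson"
        with open(paths["geojson"], "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)
    return paths


def read_assignment(path: str | Path) -> dict[str, int]:
    """Read an assignment table written by :func:`write_partition`."""
    df = pd.read_csv(path, dtype={"area_id": str})
    if "area_id" not in df.columns or "region" not in df.columns:
        raise ConfigError(f"{path}: expected 'area_id' and 'region' columns")
    return dict(zip(df["area_id"], df["region"].astype(int)))
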