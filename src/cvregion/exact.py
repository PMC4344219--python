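"""Exact solutions on tiny instances by exhaustive enumeration.

Enumerates every partition of the areas into contiguous regions (bitmask
representation, so practical up to roughly a dozen areas) and scores each
against the same feasibility rules and SSD objective as the heuristic.  Used
to certify heuristic output on small lattices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Sequence

from .preprocess import FeatureMatrix
from .regionalize import _Acc, _Problem
from .survey import AreaTable, Constraints, ContiguityGraph, Partition, VariableSpec


def _adjacency_masks(graph: ContiguityGraph, ids: Sequence[str]) -> list[int]:
    pos = {a: i for i, a in enumerate(ids)}
    masks = [0] * len(ids)
    for a in ids:
        m = 0
        for b in graph.neighbors(a):
            m |= 1 << pos[b]
        masks[pos[a]] = m
    return masks


def _is_connected(mask: int, adj: list[int]) -> bool:
    if mask == 0:
        return False
    start = mask & -mask
    seen = start
    frontier = start
    while frontier:
        nxt = 0
        m = frontier
        while m:
            bit = m & -m
            nxt |= adj[bit.bit_length() - 1]
            m ^= bit
        frontier = nxt & mask & ~seen
        seen |= frontier
    return seen == mask


def _subsets_containing_lowest(mask: int) -> Iterator[int]:
    """All submasks of *mask* that contain its lowest set bit."""
    low = mask & -mask
    rest = mask ^ low
    sub = rest
    while True:
        yield sub | low
        if sub == 0:
            return
        sub = (sub - 1) & rest


def enumerate_contiguous_partitions(graph: ContiguityGraph) -> Iterator[list[frozenset[str]]]:
    """Yield every partition of the graph's nodes into connected parts."""
    ids = sorted(graph.nodes)
    adj = _adjacency_masks(graph, ids)
    full = (1 << len(ids)) - 1
    conn_cache: dict[int, bool] = {}

    def connected(mask: int) -> bool:
        if mask not in conn_cache:
            conn_cache[mask] = _is_connected(mask, adj)
        return conn_cache[mask]

    def rec(remaining: int, parts: list[int]) -> Iterator[list[int]]:
        if remaining == 0:
            yield list(parts)
            return
        for sub in _subsets_containing_lowest(remaining):
            if connected(sub):
                parts.append(sub)
                yield from rec(remaining ^ sub, parts)
                parts.pop()

    def to_sets(parts: list[int]) -> list[frozenset[str]]:
        return [
            frozenset(ids[i] for i in range(len(ids)) if part >> i & 1) for part in parts
        ]

    for parts in rec(full, []):
        yield to_sets(parts)


@dataclass
class ExactResult:
    p_star: int
    min_ssd: float
    best: Partition
    n_feasible_partitions: int


def exact_best(
    table: AreaTable,
    graph: ContiguityGraph,
    specs: Sequence[VariableSpec],
    constraints: Constraints,
    features: FeatureMatrix,
) -> ExactResult | None:
    """Exhaustive max-p: the maximum feasible region count and, among
    partitions attaining it, the minimum SSD.  ``None`` when no feasible
    partition exists.  Only partitions whose every part is feasible are
    counted; infeasible parts prune the search.
    """
    prob = _Problem(table, graph, specs, constraints, features)
    ids = prob.ids
    adj = _adjacency_masks(graph, ids)
    full = (1 << len(ids)) - 1

    conn_cache: dict[int, bool] = {}
    part_cache: dict[int, tuple[bool, float]] = {}

    def part_info(mask: int) -> tuple[bool, float]:
        """(feasible, ssd) for one candidate part."""
        if mask not in part_cache:
            if mask not in conn_cache:
                conn_cache[mask] = _is_connected(mask, adj)
            if not conn_cache[mask]:
                part_cache[mask] = (False, math.inf)
            else:
                members = [i for i in range(len(ids)) if mask >> i & 1]
                acc = _Acc(prob, members)
                part_cache[mask] = (acc.feasible(prob), acc.ssd())
        return part_cache[mask]

    best_p = -1
    best_ssd = math.inf
    best_parts: list[int] | None = None
    n_feasible = 0

    def rec(remaining: int, parts: list[int], ssd_so_far: float) -> None:
        nonlocal best_p, best_ssd, best_parts, n_feasible
        if remaining == 0:
            n_feasible += 1
            p = len(parts)
            if p > best_p or (p == best_p and ssd_so_far < best_ssd - 1e-12):
                best_p, best_ssd, best_parts = p, ssd_so_far, list(parts)
            return
        for sub in _subsets_containing_lowest(remaining):
            ok, part_ssd = part_info(sub)
            if not ok:
                continue
            parts.append(sub)
            rec(remaining ^ sub, parts, ssd_so_far + part_ssd)
            parts.pop()

    rec(full, [], 0.0)
    if best_parts is None:
        return None
    assignment = {}
    for label, mask in enumerate(best_parts):
        for i in range(len(ids)):
            if mask >> i & 1:
                assignment[ids[i]] = label
    return ExactResult(
        p_star=best_p,
        min_ssd=best_ssd,
        best=Partition(assignment),
        n_feasible_partitions=n_feasible,
    )
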