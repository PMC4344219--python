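"""Uncertainty-constrained max-p regionalization.

The algorithm merges contiguous areas into the maximum number of regions
whose estimates all meet their coefficient-of-variation targets (plus
optional population bounds), then minimizes within-region heterogeneity.
It runs in two phases:

Phase 1 (construction, repeated ``n_starts`` times): pick a random
unassigned seed area; if it already satisfies every constraint it is a
region by itself, otherwise grow concentrically — draw uniformly at random
from the current ring of unassigned neighbors, consuming each ring before
expanding to the next — until the region becomes feasible or the frontier is
exhausted.  Areas left unassigned when no further feasible region can be
seeded are absorbed into an adjacent feasible region with the smallest
increase of the sum-of-squared-deviations (SSD) objective; if any leftover
cannot be placed, the whole attempt is discarded.  Among all feasible
partitions, the best has the most regions, ties broken by the lowest SSD.

Phase 2 (optimization): tabu search over single-area moves between adjacent
regions.  A move is admissible when the donor stays nonempty, contiguous and
feasible and the recipient stays feasible; the region count never changes.
The best admissible non-tabu move is applied each iteration (a tabu move is
allowed only when it beats the best solution ever seen); reversing a move is
tabu for ``tabu_length`` iterations.  The best solution encountered is
returned.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InfeasibleError
from .preprocess import PROPORTION_EXEMPTION_THRESHOLD, FeatureMatrix, exemption_mask
from .survey import AreaTable, Constraints, ContiguityGraph, Partition, VariableSpec
from .uncertainty import FallbackLog, region_cv_table


@dataclass(frozen=True)
class RegionalizerConfig:
    """Tuning knobs for the heuristic; identical config + seed gives
    identical output."""

    n_starts: int = 100
    rng_seed: int = 0
    tabu_length: int = 10
    max_swaps: int = 10_000
    no_improve_stop: int = 500

    def __post_init__(self) -> None:
        for name in ("n_starts", "tabu_length", "max_swaps", "no_improve_stop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Solution:
    """A feasible partition with its diagnostics."""

    partition: Partition
    ssd: float
    n_regions: int
    feasibility: dict
    phase1_candidates: int
    swap_log: int
    seed: int
    fallback_count: int = 0


# ---------------------------------------------------------------------------
# internal positional problem representation


class _Problem:
    """Positional arrays for fast feasibility and SSD evaluation.

    Region-level statistics computed here from running sums must agree with
    :func:`cvregion.uncertainty.region_cv_table`; a test enforces that.
    """

    def __init__(
        self,
        table: AreaTable,
        graph: ContiguityGraph,
        specs: Sequence[VariableSpec],
        constraints: Constraints,
        features: FeatureMatrix | None,
    ) -> None:
        if features is not None:
            self.ids = list(features.ids)
        else:
            self.ids = sorted(graph.nodes)
        if set(self.ids) != graph.nodes or set(self.ids) - set(map(str, table.df.index)):
            raise ValueError("table, graph and features must cover the same areas")
        self.pos = {a: i for i, a in enumerate(self.ids)}
        n = len(self.ids)
        self.n = n
        self.adj: list[np.ndarray] = [
            np.array(sorted(self.pos[b] for b in graph.neighbors(a)), dtype=np.intp)
            for a in self.ids
        ]
        if features is not None:
            self.F = np.asarray(features.scores, dtype=float)
            self.fsq = (self.F * self.F).sum(axis=1)
        else:
            self.F = np.zeros((n, 1))
            self.fsq = np.zeros(n)
        df = table.df.loc[self.ids]
        self.pop = df[table.pop_est_col].to_numpy(float)
        self.specs = list(specs)
        j = len(self.specs)
        self.targets = np.array([constraints.cv_target(s) for s in self.specs])
        self.is_derived = np.array([s.kind != "count" for s in self.specs])
        self.is_prop = np.array([s.kind == "proportion" for s in self.specs])
        self.is_mean = np.array([s.kind == "mean" for s in self.specs])
        from .uncertainty import Z90

        self.ne = np.zeros((j, n))
        self.nv = np.zeros((j, n))
        self.de = np.zeros((j, n))
        self.dv = np.zeros((j, n))
        for jj, s in enumerate(self.specs):
            self.ne[jj] = df[s.num_est].to_numpy(float)
            self.nv[jj] = (df[s.num_moe].to_numpy(float) / Z90) ** 2
            if s.den_est is not None:
                self.de[jj] = df[s.den_est].to_numpy(float)
                self.dv[jj] = (df[s.den_moe].to_numpy(float) / Z90) ** 2
        self.pop_min = constraints.population_min if constraints.population_min is not None else -math.inf
        self.pop_max = constraints.population_max if constraints.population_max is not None else math.inf

    # -- region statistics from running sums ------------------------------

    def stats(self, ne, nv, de, dv):
        """Per-variable (estimate, se, cv, exempt) arrays for aggregated sums."""
        j = len(self.specs)
        est = np.empty(j)
        se = np.empty(j)
        cvs = np.empty(j)
        for k in range(j):
            if self.is_derived[k]:
                if de[k] <= 0:
                    est[k], se[k], cvs[k] = math.nan, math.nan, math.inf
                    continue
                p = ne[k] / de[k]
                if self.is_prop[k]:
                    rad = nv[k] - p * p * dv[k]
                    if rad < 0:
                        rad = nv[k] + p * p * dv[k]
                else:
                    rad = nv[k] + p * p * dv[k]
                est[k] = p
                # running sums can drift a few ulps below zero
                se[k] = math.sqrt(max(rad, 0.0)) / de[k]
            else:
                est[k] = ne[k]
                se[k] = math.sqrt(max(nv[k], 0.0))
            if est[k] > 0:
                cvs[k] = se[k] / est[k]
            else:
                cvs[k] = 0.0 if se[k] == 0 else math.inf
        exempt = self.is_prop & (est < PROPORTION_EXEMPTION_THRESHOLD)
        return est, se, cvs, exempt

    def feasible_sums(self, ne, nv, de, dv, pop) -> bool:
        if not (self.pop_min <= pop <= self.pop_max):
            return False
        _, _, cvs, exempt = self.stats(ne, nv, de, dv)
        return bool(np.all(exempt | (cvs <= self.targets)))

    def connected_without(self, members: set[int], removed: int) -> bool:
        """Does the member set stay connected after removing one area?"""
        rest = members - {removed}
        if not rest:
            return False
        start = next(iter(rest))
        seen = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in self.adj[u]:
                v = int(v)
                if v in rest and v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == len(rest)


class _Acc:
    """Running aggregates for one region."""

    __slots__ = ("ne", "nv", "de", "dv", "pop", "s", "q", "n")

    def __init__(self, prob: _Problem, members: Sequence[int] = ()) -> None:
        j = len(prob.specs)
        self.ne = np.zeros(j)
        self.nv = np.zeros(j)
        self.de = np.zeros(j)
        self.dv = np.zeros(j)
        self.pop = 0.0
        self.s = np.zeros(prob.F.shape[1])
        self.q = 0.0
        self.n = 0
        for i in members:
            self.add(prob, i)

    def add(self, prob: _Problem, i: int) -> None:
        self.ne += prob.ne[:, i]
        self.nv += prob.nv[:, i]
        self.de += prob.de[:, i]
        self.dv += prob.dv[:, i]
        self.pop += prob.pop[i]
        self.s += prob.F[i]
        self.q += prob.fsq[i]
        self.n += 1

    def remove(self, prob: _Problem, i: int) -> None:
        self.ne -= prob.ne[:, i]
        self.nv -= prob.nv[:, i]
        self.de -= prob.de[:, i]
        self.dv -= prob.dv[:, i]
        self.pop -= prob.pop[i]
        self.s -= prob.F[i]
        self.q -= prob.fsq[i]
        self.n -= 1

    def feasible(self, prob: _Problem) -> bool:
        return prob.feasible_sums(self.ne, self.nv, self.de, self.dv, self.pop)

    def feasible_with(self, prob: _Problem, i: int) -> bool:
        return prob.feasible_sums(
            self.ne + prob.ne[:, i],
            self.nv + prob.nv[:, i],
            self.de + prob.de[:, i],
            self.dv + prob.dv[:, i],
            self.pop + prob.pop[i],
        )

    def feasible_without(self, prob: _Problem, i: int) -> bool:
        return prob.feasible_sums(
            self.ne - prob.ne[:, i],
            self.nv - prob.nv[:, i],
            self.de - prob.de[:, i],
            self.dv - prob.dv[:, i],
            self.pop - prob.pop[i],
        )

    def ssd(self) -> float:
        if self.n == 0:
            return 0.0
        return float(self.q - self.s @ self.s / self.n)

    def ssd_with(self, prob: _Problem, i: int) -> float:
        s = self.s + prob.F[i]
        return float(self.q + prob.fsq[i] - s @ s / (self.n + 1))

    def ssd_without(self, prob: _Problem, i: int) -> float:
        if self.n <= 1:
            return 0.0
        s = self.s - prob.F[i]
        return float(self.q - prob.fsq[i] - s @ s / (self.n - 1))


# ---------------------------------------------------------------------------
# phase 1: randomized construction


def _grow(prob: _Problem, rng: np.random.Generator) -> tuple[list[list[int]], list[int]]:
    """One randomized construction pass: seed, grow concentrically, repeat."""
    unassigned = np.ones(prob.n, dtype=bool)
    tried = np.zeros(prob.n, dtype=bool)
    regions: list[list[int]] = []
    while True:
        cand = np.flatnonzero(unassigned & ~tried)
        if cand.size == 0:
            break
        seed = int(rng.choice(cand))
        tried[seed] = True
        members = [seed]
        member_set = {seed}
        acc = _Acc(prob, members)
        feasible = acc.feasible(prob)
        ring: list[int] = []
        aborted = False
        while not feasible:
            if acc.pop > prob.pop_max:
                aborted = True  # population ceiling can never be recovered by growing
                break
            if not ring:
                frontier = {
                    int(v)
                    for m in members
                    for v in prob.adj[m]
                    if unassigned[v] and int(v) not in member_set
                }
                if not frontier:
                    aborted = True  # exhausted without reaching feasibility
                    break
                ring = sorted(frontier)
                rng.shuffle(ring)
            nxt = ring.pop()
            members.append(nxt)
            member_set.add(nxt)
            acc.add(prob, nxt)
            feasible = acc.feasible(prob)
        if feasible and not aborted:
            for m in members:
                unassigned[m] = False
            regions.append(members)
    return regions, [int(i) for i in np.flatnonzero(unassigned)]


def _assign_leftovers(
    prob: _Problem,
    regions: list[list[int]],
    leftovers: list[int],
    rng: np.random.Generator,
) -> list[list[int]] | None:
    """Absorb leftover areas into adjacent regions, least SSD increase first.

    Leftovers whose only neighbors are other still-unplaced leftovers are
    requeued; if a full cycle makes no progress the attempt fails.
    """
    label_of = {i: k for k, r in enumerate(regions) for i in r}
    accs = [_Acc(prob, r) for r in regions]
    members = [list(r) for r in regions]
    queue = deque(leftovers)
    # rng.shuffle works on lists, not deques
    order = list(queue)
    rng.shuffle(order)
    queue = deque(order)
    stall = 0
    while queue:
        i = queue.popleft()
        neighbor_regions = sorted({label_of[int(v)] for v in prob.adj[i] if int(v) in label_of})
        best_k, best_delta = None, math.inf
        for k in neighbor_regions:
            if not accs[k].feasible_with(prob, i):
                continue
            delta = accs[k].ssd_with(prob, i) - accs[k].ssd()
            if delta < best_delta:
                best_k, best_delta = k, delta
        if best_k is None:
            pending = set(queue)
            if any(int(v) in pending for v in prob.adj[i]):
                queue.append(i)
                stall += 1
                if stall > len(queue):
                    return None
                continue
            return None
        accs[best_k].add(prob, i)
        members[best_k].append(i)
        label_of[i] = best_k
        stall = 0
    return members


def _partition_ssd(prob: _Problem, regions: list[list[int]]) -> float:
    return sum(_Acc(prob, r).ssd() for r in regions)


# ---------------------------------------------------------------------------
# phase 2: tabu search


def _tabu(
    prob: _Problem,
    regions: list[list[int]],
    config: RegionalizerConfig,
) -> tuple[list[list[int]], float, int]:
    """Tabu-search improvement of a feasible partition.

    Returns (best regions, best ssd, accepted-move count)."""
    label_of = np.empty(prob.n, dtype=np.intp)
    members: list[set[int]] = []
    for k, r in enumerate(regions):
        members.append(set(r))
        for i in r:
            label_of[i] = k
    accs = [_Acc(prob, r) for r in regions]
    ssd_total = sum(a.ssd() for a in accs)
    best_ssd = ssd_total
    best_labels = label_of.copy()
    tabu_until: dict[tuple[int, int], int] = {}
    swaps = 0
    no_improve = 0
    iteration = 0
    eps = 1e-12

    while swaps < config.max_swaps and no_improve < config.no_improve_stop:
        iteration += 1
        best_move = None  # (delta, i, A, B)
        for i in range(prob.n):
            A = int(label_of[i])
            if len(members[A]) == 1:
                continue
            targets = sorted({int(label_of[int(v)]) for v in prob.adj[i]} - {A})
            if not targets:
                continue
            donor_checked = None
            for B in targets:
                tabu = tabu_until.get((i, B), 0) > iteration
                if donor_checked is None:
                    donor_checked = accs[A].feasible_without(prob, i) and prob.connected_without(
                        members[A], i
                    )
                if not donor_checked:
                    break
                if not accs[B].feasible_with(prob, i):
                    continue
                delta = (
                    accs[A].ssd_without(prob, i)
                    - accs[A].ssd()
                    + accs[B].ssd_with(prob, i)
                    - accs[B].ssd()
                )
                if tabu and not (ssd_total + delta < best_ssd - eps):
                    continue  # tabu and no aspiration
                if best_move is None or delta < best_move[0] - eps:
                    best_move = (delta, i, A, B)
        if best_move is None:
            break
        delta, i, A, B = best_move
        accs[A].remove(prob, i)
        accs[B].add(prob, i)
        members[A].discard(i)
        members[B].add(i)
        label_of[i] = B
        tabu_until[(i, A)] = iteration + config.tabu_length
        ssd_total += delta
        swaps += 1
        if ssd_total < best_ssd - eps:
            best_ssd = ssd_total
            best_labels = label_of.copy()
            no_improve = 0
        else:
            no_improve += 1

    out: dict[int, list[int]] = {}
    for i, lab in enumerate(best_labels):
        out.setdefault(int(lab), []).append(i)
    best_regions = [out[k] for k in sorted(out)]
    return best_regions, _partition_ssd(prob, best_regions), swaps


# ---------------------------------------------------------------------------
# public operations


def region_feasible(
    region,
    table: AreaTable,
    specs: Sequence[VariableSpec],
    constraints: Constraints,
) -> tuple[bool, dict]:
    """Check one candidate region against CV and population constraints.

    Returns (feasible, report); the report gives per-variable estimate, CV,
    target and exemption status plus the population check.  This is the
    row-based reference path built on :func:`region_cv_table`; the optimizer
    uses an equivalent running-sum evaluator.
    """
    members = sorted(region)
    stats = region_cv_table(members, table, specs)
    estimates = {name: est for name, (est, _, _) in stats.items()}
    exempt = exemption_mask(estimates, specs)
    report: dict = {"variables": {}, "feasible": True}
    for spec in specs:
        est, se, cval = stats[spec.name]
        target = constraints.cv_target(spec)
        ok = exempt[spec.name] or cval <= target
        report["variables"][spec.name] = {
            "estimate": est,
            "se": se,
            "cv": cval,
            "target": target,
            "exempt": exempt[spec.name],
            "ok": ok,
        }
        if not ok:
            report["feasible"] = False
    pop = sum(table.population(a) for a in members)
    report["population"] = pop
    pop_ok = True
    if constraints.population_min is not None and pop < constraints.population_min:
        pop_ok = False
    if constraints.population_max is not None and pop > constraints.population_max:
        pop_ok = False
    report["population_ok"] = pop_ok
    if not pop_ok:
        report["feasible"] = False
    return report["feasible"], report


def _regions_to_partition(prob: _Problem, regions: list[list[int]]) -> Partition:
    assignment = {}
    for label, r in enumerate(regions):
        for i in r:
            assignment[prob.ids[i]] = label
    return Partition(assignment)


def grow_partition(
    graph: ContiguityGraph,
    table: AreaTable,
    specs: Sequence[VariableSpec],
    constraints: Constraints,
    rng: np.random.Generator,
    features: FeatureMatrix | None = None,
) -> tuple[Partition | None, list[str]]:
    """One randomized seeded-growth pass (no leftover assignment).

    Returns the partial partition over assigned areas (``None`` when no
    feasible region could be built) and the leftover area ids.
    """
    prob = _Problem(table, graph, specs, constraints, features)
    regions, leftovers = _grow(prob, rng)
    left_ids = [prob.ids[i] for i in leftovers]
    if not regions:
        return None, left_ids
    return _regions_to_partition(prob, regions), left_ids


def assign_leftovers(
    partition: Partition,
    leftovers: Sequence[str],
    graph: ContiguityGraph,
    table: AreaTable,
    specs: Sequence[VariableSpec],
    constraints: Constraints,
    features: FeatureMatrix,
    rng: np.random.Generator | None = None,
) -> Partition | None:
    """Absorb leftover areas into adjacent regions (least SSD increase).

    Returns ``None`` when some leftover has no feasible adjacent region."""
    prob = _Problem(table, graph, specs, constraints, features)
    label_order = sorted(partition.regions)
    regions = [
        [prob.pos[a] for a in sorted(partition.regions[lab])] for lab in label_order
    ]
    left = [prob.pos[a] for a in leftovers]
    rng = rng if rng is not None else np.random.default_rng(0)
    out = _assign_leftovers(prob, regions, left, rng)
    if out is None:
        return None
    return _regions_to_partition(prob, out)


def best_partition(candidates: Sequence[Partition]) -> Partition:
    """Most regions wins; ties broken by lowest SSD, then earliest candidate."""
    if not candidates:
        raise InfeasibleError(
            "no feasible partition found; relax the CV target or population bounds"
        )
    best = candidates[0]
    for cand in candidates[1:]:
        if cand.n_regions > best.n_regions or (
            cand.n_regions == best.n_regions and cand.ssd < best.ssd
        ):
            best = cand
    return best


def ssd(partition: Partition, features: FeatureMatrix) -> float:
    """Sum of squared deviations of weighted feature scores from region means."""
    idx = features.row_index()
    total = 0.0
    for members in partition.regions.values():
        rows = features.scores[[idx[a] for a in members]]
        total += float(((rows - rows.mean(axis=0)) ** 2).sum())
    return total


def tabu_improve(
    solution: Solution,
    features: FeatureMatrix,
    graph: ContiguityGraph,
    table: AreaTable,
    specs: Sequence[VariableSpec],
    constraints: Constraints,
    config: RegionalizerConfig,
) -> Solution:
    """Tabu-search swap optimization of a feasible solution (region count fixed)."""
    prob = _Problem(table, graph, specs, constraints, features)
    label_order = sorted(solution.partition.regions)
    regions = [
        sorted(prob.pos[a] for a in solution.partition.regions[lab]) for lab in label_order
    ]
    best_regions, best_ssd, swaps = _tabu(prob, regions, config)
    part = _regions_to_partition(prob, best_regions)
    return _finalize(prob, table, specs, constraints, part, best_ssd,
                     solution.phase1_candidates, solution.swap_log + swaps,
                     solution.seed)


def _finalize(
    prob: _Problem,
    table: AreaTable,
    specs: Sequence[VariableSpec],
    constraints: Constraints,
    partition: Partition,
    ssd_value: float,
    phase1_candidates: int,
    swaps: int,
    seed: int,
) -> Solution:
    from .survey import compute_region_table

    fallback = FallbackLog()
    feas: dict = {}
    for label in sorted(partition.regions):
        ok, report = region_feasible(
            partition.regions[label], table, specs, constraints
        )
        # re-run the aggregation once with fallback logging for the manifest
        region_cv_table(sorted(partition.regions[label]), table, specs, fallback)
        feas[int(label)] = report
        assert ok, f"internal error: returned region {label} is infeasible"
    partition.region_table = compute_region_table(partition, table, specs)
    partition.ssd = ssd_value
    return Solution(
        partition=partition,
        ssd=ssd_value,
        n_regions=partition.n_regions,
        feasibility=feas,
        phase1_candidates=phase1_candidates,
        swap_log=swaps,
        seed=seed,
        fallback_count=fallback.count,
    )


def regionalize(
    table: AreaTable,
    graph: ContiguityGraph,
    specs: Sequence[VariableSpec],
    constraints: Constraints,
    config: RegionalizerConfig | None = None,
    features: FeatureMatrix | None = None,
) -> Solution:
    """Full pipeline: repeated construction, best-partition pick, tabu polish.

    *table* and *features* are assumed preprocessed (zero-household areas
    dropped, zero-estimate MOEs reset, features from the weighted-PCA
    pipeline).  Raises :class:`InfeasibleError` when no attempt produces a
    feasible partition.
    """
    config = config or RegionalizerConfig()
    constraints.validate(specs)
    if features is None:
        from .preprocess import attribute_matrix, pca_features, zscore

        features = pca_features(zscore(attribute_matrix(table, specs)))
    prob = _Problem(table, graph, specs, constraints, features)
    rng = np.random.default_rng(config.rng_seed)
    candidates: list[tuple[int, float, list[list[int]]]] = []
    for _ in range(config.n_starts):
        regions, leftovers = _grow(prob, rng)
        if not regions:
            continue
        complete = _assign_leftovers(prob, regions, leftovers, rng)
        if complete is None:
            continue
        candidates.append(
            (len(complete), _partition_ssd(prob, complete), complete)
        )
    if not candidates:
        raise InfeasibleError(
            "no feasible partition found in "
            f"{config.n_starts} attempts; relax the CV target or population bounds"
        )
    best = candidates[0]
    for cand in candidates[1:]:
        if cand[0] > best[0] or (cand[0] == best[0] and cand[1] < best[1] - 1e-12):
            best = cand
    regions = best[2]
    best_regions, best_ssd, swaps = _tabu(prob, regions, config)
    partition = _regions_to_partition(prob, best_regions)
    sol = _finalize(
        prob, table, specs, constraints, partition, best_ssd,
        len(candidates), swaps, config.rng_seed,
    )
    # cached SSD must match a from-scratch recomputation
    assert abs(sol.ssd - ssd(sol.partition, features)) <= 1e-9 * max(1.0, sol.ssd)
    return sol
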