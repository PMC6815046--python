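"""Assembly of a seed-centred gene module from candidate seed pathways.

Candidate paths are clustered by a weight-proportional random walk on a
path-overlap graph (vertices are paths; edges join paths sharing genes,
weighted by Jaccard similarity of their gene sets).  Each walk's union
of visited gene sets is a candidate module, which local search repairs
to feasibility and then improves by steepest-ascent hill climbing over
single-gene add / remove / swap moves, maximising the standardised
module score

    S_M = sum_{i in M} s_i / sqrt(|M|)

subject to module size bounds, a minimum mean absolute co-expression
with the seed over non-seed members, a minimum PPI edge density, and
connectivity of the induced PPI subgraph.  Discovery sweeps a grid of
constraint settings and returns the highest-scoring feasible module,
or a defined failure (no admissible paths, or constraints infeasible).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from seedmod.errors import SeedNotInUniverseError
from seedmod.network_io import CoexpressionMatrix
from seedmod.pathfinding import PathSet, enumerate_paths
from seedmod.seed_scoring import SeedScoreVector

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass(frozen=True)
class Constraints:
    """Feasibility constraints for one grid cell of the parameter sweep."""

    size_min: int
    size_max: int
    min_avg_coexpr: float
    min_ppi_density: float

    def __post_init__(self) -> None:
        if self.size_min < 2:
            raise ValueError("size_min must be >= 2")
        if self.size_max < self.size_min:
            raise ValueError("size_max must be >= size_min")
        if not (0.0 <= self.min_avg_coexpr <= 1.0):
            raise ValueError("min_avg_coexpr must be in [0, 1]")
        if not (0.0 <= self.min_ppi_density <= 1.0):
            raise ValueError("min_ppi_density must be in [0, 1]")


#: Default parameter sweep: module size bands x minimum seed co-expression
#: x minimum PPI density.
DEFAULT_GRID: list[Constraints] = [
    Constraints(lo, hi, c, d)
    for (lo, hi) in [(20, 40), (40, 80), (60, 100)]
    for c in (0.4, 0.5, 0.6)
    for d in (0.05, 0.10, 0.15)
]


@dataclass(frozen=True)
class Failure:
    """Discovery failure with a machine-readable reason."""

    reason: str  # "no_paths" | "constraint_infeasible"


@dataclass
class GeneModule:
    """A discovered module with its score and constraint diagnostics."""

    seed: str
    genes: frozenset
    score: float
    avg_coexpr: float
    ppi_density: float
    constraints_used: Constraints
    rng_seed: int | None = None

    @property
    def size(self) -> int:
        return len(self.genes)

    def sorted_genes(self) -> list[str]:
        return sorted(self.genes)

    def to_tsv(self, path, scores: SeedScoreVector, corr: CoexpressionMatrix, graph: nx.Graph) -> None:
        lines = [
            f"# seed={self.seed}",
            f"# S_M={self.score:.10g}",
            f"# size={self.size}",
            f"# avg_coexpr={self.avg_coexpr:.10g}",
            f"# ppi_density={self.ppi_density:.10g}",
            f"# constraints=size[{self.constraints_used.size_min},{self.constraints_used.size_max}]"
            f",min_avg_coexpr={self.constraints_used.min_avg_coexpr}"
            f",min_ppi_density={self.constraints_used.min_ppi_density}",
            f"# rng_seed={self.rng_seed}",
            "gene\tscore\tabs_corr_seed\tdegree_in_module",
        ]
        sub = graph.subgraph(self.genes)
        for g in self.sorted_genes():
            lines.append(
                f"{g}\t{scores.scores[g]:.10g}\t{abs(corr.loc(g, self.seed)):.10g}\t{sub.degree(g)}"
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


@dataclass
class DiscoveryOutcome:
    """Either a discovered GeneModule or a Failure record (never both)."""

    module: GeneModule | None = None
    failure: Failure | None = None
    cells_tried: int = 0

    def __post_init__(self) -> None:
        if (self.module is None) == (self.failure is None):
            raise ValueError("exactly one of module/failure must be set")

    @property
    def ok(self) -> bool:
        return self.module is not None


def module_score(genes, scores: SeedScoreVector) -> float:
    """Standardised module score S_M = sum of member scores / sqrt(size)."""
    genes = set(genes)
    if not genes:
        raise ValueError("module is empty")
    total = 0.0
    for g in genes:
        if g not in scores.scores:
            raise KeyError(f"gene {g!r} has no score")
        total += scores.scores[g]
    return total / math.sqrt(len(genes))


def build_path_graph(paths: PathSet, overlap_min: int = 1) -> nx.Graph:
    """Graph over candidate paths; edges join paths sharing >= overlap_min genes.

    Edge weight is the Jaccard similarity of the two gene sets.
    """
    if len(paths) == 0:
        raise ValueError("path set is empty")
    pg = nx.Graph()
    gene_sets = [p.gene_set for p in paths.paths]
    for i, p in enumerate(paths.paths):
        pg.add_node(i, path=p)
    for i, j in combinations(range(len(gene_sets)), 2):
        inter = len(gene_sets[i] & gene_sets[j])
        if inter >= overlap_min:
            union = len(gene_sets[i] | gene_sets[j])
            pg.add_edge(i, j, weight=inter / union)
    return pg


def random_walk_cluster(
    pg: nx.Graph,
    walk_len: int = 4,
    n_walks: int = 1,
    rng_seed: int = 0,
) -> list[frozenset]:
    """Weight-proportional random walks on the path graph yield candidate gene sets.

    From every vertex, ``n_walks`` walks of ``walk_len`` steps are taken,
    each step moving to a neighbour with probability proportional to the
    edge weight; the union of gene sets of all visited paths forms one
    candidate.  Duplicate candidates are removed.  Deterministic for a
    fixed ``rng_seed``.
    """
    if pg.number_of_nodes() == 0:
        raise ValueError("path graph is empty")
    rng = np.random.default_rng(rng_seed)
    candidates: dict[frozenset, None] = {}
    for start in sorted(pg.nodes()):
        for _ in range(n_walks):
            genes = set(pg.nodes[start]["path"].gene_set)
            current = start
            for _ in range(walk_len):
                nbrs = sorted(pg.neighbors(current))
                if not nbrs:
                    break
                weights = np.array([pg[current][n]["weight"] for n in nbrs])
                current = nbrs[int(rng.choice(len(nbrs), p=weights / weights.sum()))]
                genes |= pg.nodes[current]["path"].gene_set
            candidates.setdefault(frozenset(genes))
    return sorted(candidates, key=lambda s: (len(s), tuple(sorted(s))))


class _ModuleState:
    """Incremental bookkeeping for local search over one gene set."""

    def __init__(self, genes, seed, scores, abs_corr, graph):
        self.seed = seed
        self.scores = scores
        self.abs_corr = abs_corr
        self.graph = graph
        self.members = set(genes)
        self.s_sum = sum(scores.scores[g] for g in self.members)
        self.corr_sum = sum(abs_corr[g] for g in self.members if g != seed)
        self.n_edges = sum(
            1 for a, b in combinations(sorted(self.members), 2) if graph.has_edge(a, b)
        )

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def score(self) -> float:
        return self.s_sum / math.sqrt(self.size)

    @property
    def avg_coexpr(self) -> float:
        non_seed = self.size - 1
        return self.corr_sum / non_seed if non_seed else 1.0

    @property
    def density(self) -> float:
        pairs = self.size * (self.size - 1) / 2
        return self.n_edges / pairs if pairs else 0.0

    def deg_in(self, gene: str) -> int:
        return sum(1 for n in self.graph.neighbors(gene) if n in self.members and n != gene)

    def add(self, gene: str) -> None:
        self.n_edges += self.deg_in(gene)
        self.members.add(gene)
        self.s_sum += self.scores.scores[gene]
        self.corr_sum += self.abs_corr[gene]

    def remove(self, gene: str) -> None:
        self.members.remove(gene)
        self.n_edges -= self.deg_in(gene)
        self.s_sum -= self.scores.scores[gene]
        self.corr_sum -= self.abs_corr[gene]

    def is_connected(self) -> bool:
        sub = self.graph.subgraph(self.members)
        return self.size > 0 and nx.is_connected(sub)

    def removable(self) -> set:
        """Non-seed members whose removal keeps the induced subgraph connected."""
        sub = self.graph.subgraph(self.members)
        if self.size <= 1 or not nx.is_connected(sub):
            return set()
        arts = set(nx.articulation_points(sub))
        return {g for g in self.members if g != self.seed and g not in arts}

    def frontier(self) -> set:
        """Eligible scored non-member genes adjacent to the module."""
        out = set()
        for g in self.members:
            for n in self.graph.neighbors(g):
                if (
                    n not in self.members
                    and self.scores.is_eligible(n)
                    and n in self.scores.scores
                ):
                    out.add(n)
        return out

    def feasible(self, c: Constraints) -> bool:
        return (
            c.size_min <= self.size <= c.size_max
            and self.avg_coexpr >= c.min_avg_coexpr - _EPS
            and self.density >= c.min_ppi_density - _EPS
            and self.is_connected()
        )


def _repair(state: _ModuleState, c: Constraints, max_steps: int) -> bool:
    """Greedy repair toward feasibility; one gene move per step.

    For each violated constraint the non-seed gene whose removal (or the
    frontier gene whose addition, for the lower size bound) most improves
    that constraint is applied, preserving connectivity throughout.
    """
    seed = state.seed
    # keep only the component containing the seed
    sub = state.graph.subgraph(state.members)
    comp = set(nx.node_connected_component(sub, seed))
    if comp != state.members:
        state.__init__(comp, seed, state.scores, state.abs_corr, state.graph)

    for _ in range(max_steps):
        if state.feasible(c):
            return True
        removable = state.removable()
        if state.size > c.size_max:
            if not removable:
                return False
            # dropping the weakest seed-co-expression gene tightens size and
            # tends to help the co-expression constraint too
            g = min(removable, key=lambda g: (state.abs_corr[g], g))
            state.remove(g)
            continue
        if state.avg_coexpr < c.min_avg_coexpr - _EPS:
            below = [g for g in removable if state.abs_corr[g] < state.avg_coexpr]
            if not below or state.size - 1 < c.size_min:
                return False
            g = min(below, key=lambda g: (state.abs_corr[g], g))
            state.remove(g)
            continue
        if state.density < c.min_ppi_density - _EPS:
            # removing a low-degree gene raises density when its within-degree
            # is below the module average
            helpful = [g for g in removable if state.deg_in(g) * state.size < 2 * state.n_edges]
            if not helpful or state.size - 1 < c.size_min:
                return False
            g = min(helpful, key=lambda g: (state.deg_in(g), g))
            state.remove(g)
            continue
        if state.size < c.size_min:
            frontier = state.frontier()
            if not frontier:
                return False
            # prefer high seed co-expression additions to protect avg_coexpr
            g = max(frontier, key=lambda g: (state.abs_corr[g], state.scores.scores[g], g))
            state.add(g)
            continue
        return state.feasible(c)
    return state.feasible(c)


def local_search(
    candidate,
    scores: SeedScoreVector,
    corr: CoexpressionMatrix,
    graph: nx.Graph,
    constraints: Constraints,
    max_iter: int = 200,
    rng_seed: int | None = None,
) -> GeneModule | Failure:
    """Repair a candidate gene set to feasibility, then hill-climb S_M.

    Steepest-ascent over single-gene moves (add an eligible PPI
    neighbour, remove a non-seed gene, or swap one for the other); a
    move is accepted only if S_M strictly increases and every constraint
    stays satisfied.  Ties between equally improving moves are broken by
    the lexicographically smallest gene symbol involved.  The search is
    deterministic; ``rng_seed`` is recorded for provenance only.
    """
    seed = scores.seed
    candidate = set(candidate)
    if seed not in candidate:
        raise ValueError("candidate must contain the seed gene")
    abs_corr = {g: abs(corr.loc(g, seed)) for g in scores.scores}
    state = _ModuleState(candidate, seed, scores, abs_corr, graph)
    if not _repair(state, constraints, max_steps=2 * len(candidate) + 50):
        return Failure("constraint_infeasible")

    c = constraints
    for _ in range(max_iter):
        cur = state.score
        sqrt_n = math.sqrt(state.size)
        sqrt_np1 = math.sqrt(state.size + 1)
        sqrt_nm1 = math.sqrt(state.size - 1) if state.size > 1 else 1.0
        best = None  # (delta, tie_key, kind, payload)

        frontier = sorted(state.frontier())
        removable = sorted(state.removable())
        deg_in = {g: state.deg_in(g) for g in frontier}

        # adds
        if state.size + 1 <= c.size_max:
            n = state.size
            pairs_new = (n + 1) * n / 2
            for g in frontier:
                new_score = (state.s_sum + scores.scores[g]) / sqrt_np1
                delta = new_score - cur
                if delta <= _EPS:
                    continue
                if (state.corr_sum + abs_corr[g]) / n < c.min_avg_coexpr - _EPS:
                    continue
                if (state.n_edges + deg_in[g]) / pairs_new < c.min_ppi_density - _EPS:
                    continue
                move = (delta, (g,), "add", g)
                if best is None or _better(move, best):
                    best = move

        # removes
        if state.size - 1 >= c.size_min:
            n = state.size
            pairs_new = (n - 1) * (n - 2) / 2
            for g in removable:
                new_score = (state.s_sum - scores.scores[g]) / sqrt_nm1
                delta = new_score - cur
                if delta <= _EPS:
                    continue
                if n - 2 > 0 and (state.corr_sum - abs_corr[g]) / (n - 2) < c.min_avg_coexpr - _EPS:
                    continue
                if pairs_new > 0 and (state.n_edges - state.deg_in(g)) / pairs_new < c.min_ppi_density - _EPS:
                    continue
                move = (delta, (g,), "remove", g)
                if best is None or _better(move, best):
                    best = move

        # swaps (size-preserving)
        n = state.size
        pairs = n * (n - 1) / 2
        for r in removable:
            deg_r = state.deg_in(r)
            s_r = scores.scores[r]
            for g in frontier:
                if scores.scores[g] - s_r <= _EPS * sqrt_n:
                    continue
                delta = (scores.scores[g] - s_r) / sqrt_n
                if best is not None and delta < best[0] - _EPS:
                    continue
                # g must stay attached once r is gone
                deg_g = deg_in[g] - (1 if state.graph.has_edge(g, r) else 0)
                if deg_g < 1:
                    continue
                if n - 1 > 0 and (state.corr_sum - abs_corr[r] + abs_corr[g]) / (n - 1) < c.min_avg_coexpr - _EPS:
                    continue
                if pairs > 0 and (state.n_edges - deg_r + deg_g) / pairs < c.min_ppi_density - _EPS:
                    continue
                move = (delta, tuple(sorted((r, g))), "swap", (r, g))
                if best is None or _better(move, best):
                    best = move

        if best is None:
            break
        _, _, kind, payload = best
        if kind == "add":
            state.add(payload)
        elif kind == "remove":
            state.remove(payload)
        else:
            r, g = payload
            state.remove(r)
            state.add(g)
        if not state.is_connected():  # swap may disconnect via removed bridge
            # revert and stop; the accepted move set guards should prevent this
            if kind == "swap":
                r, g = payload
                state.remove(g)
                state.add(r)
            break

    if not state.feasible(c):
        return Failure("constraint_infeasible")
    return GeneModule(
        seed=seed,
        genes=frozenset(state.members),
        score=module_score(state.members, scores),
        avg_coexpr=state.avg_coexpr,
        ppi_density=state.density,
        constraints_used=constraints,
        rng_seed=rng_seed,
    )


def _better(move, best) -> bool:
    """Strictly larger gain wins; exact ties go to the smaller gene symbols."""
    if move[0] > best[0] + _EPS:
        return True
    if move[0] < best[0] - _EPS:
        return False
    return move[1] < best[1]


def discover_module(
    seed: str,
    corr: CoexpressionMatrix,
    graph: nx.Graph,
    scores: SeedScoreVector,
    grid: list[Constraints] | None = None,
    *,
    len_min: int = 5,
    len_max: int = 8,
    K: int = 1000,
    n_restarts: int = 5000,
    overlap_min: int = 1,
    walk_len: int = 4,
    n_walks: int = 1,
    max_candidates: int = 10,
    max_iter: int = 200,
    rng_seed: int = 0,
) -> DiscoveryOutcome:
    """Run the full discovery pipeline for one seed over a constraint grid.

    Paths and random-walk candidates are computed once; local search runs
    per grid cell.  Among all feasible modules the one with maximal S_M
    is returned (ties: smaller module, then lexicographic gene list).
    The master ``rng_seed`` deterministically derives per-stage seeds.
    """
    if grid is None:
        grid = DEFAULT_GRID
    if seed not in corr.genes:
        raise SeedNotInUniverseError(f"seed gene {seed!r} not in universe")
    if scores.seed != seed:
        raise ValueError("score vector was computed for a different seed")

    path_seed, walk_seed = (
        int(s) for s in np.random.SeedSequence(rng_seed).generate_state(2)
    )

    # a module's mean |corr to seed| cannot exceed the best single gene's
    max_corr = max(
        (abs(corr.loc(g, seed)) for g in corr.genes if g != seed), default=0.0
    )
    live_grid = [c for c in grid if max_corr >= c.min_avg_coexpr - _EPS]
    if not live_grid:
        return DiscoveryOutcome(failure=Failure("constraint_infeasible"))

    paths = enumerate_paths(
        graph,
        scores,
        len_min=len_min,
        len_max=len_max,
        K=K,
        n_restarts=n_restarts,
        rng_seed=path_seed,
    )
    if len(paths) == 0:
        return DiscoveryOutcome(failure=Failure("no_paths"))

    pg = build_path_graph(paths, overlap_min=overlap_min)
    candidates = random_walk_cluster(pg, walk_len=walk_len, n_walks=n_walks, rng_seed=walk_seed)
    candidates.sort(key=lambda s: (-module_score(s, scores), tuple(sorted(s))))
    candidates = candidates[:max_candidates]

    best: GeneModule | None = None
    tried = 0
    for c in live_grid:
        for cand in candidates:
            tried += 1
            result = local_search(
                set(cand) | {seed}, scores, corr, graph, c,
                max_iter=max_iter, rng_seed=rng_seed,
            )
            if isinstance(result, Failure):
                continue
            if best is None or _module_key(result) < _module_key(best):
                best = result
    if best is None:
        return DiscoveryOutcome(failure=Failure("constraint_infeasible"), cells_tried=tried)
    best.rng_seed = rng_seed
    return DiscoveryOutcome(module=best, cells_tried=tried)


def _module_key(m: GeneModule):
    return (-m.score, m.size, tuple(sorted(m.genes)))
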