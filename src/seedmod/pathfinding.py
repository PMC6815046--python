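"""Enumeration of high-scoring simple "seed pathways" in the PPI graph.

A seed pathway is a simple path of ``len_min``-``len_max`` genes (node
count; defaults 5-8) through the interaction graph, rooted at the seed
gene, using only eligible genes, and valued by the sum of member gene
scores.  On small graphs all such paths are enumerated exhaustively;
otherwise a randomized depth-limited search repeatedly grows paths from
the seed, extending to an unvisited eligible neighbour chosen with
probability proportional to its score, and records every prefix of
admissible length.  The top-K paths with distinct gene sets are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from seedmod.seed_scoring import SeedScoreVector

#: Node-count threshold at or below which exhaustive enumeration replaces
#: the randomized search.
EXHAUSTIVE_NODE_THRESHOLD = 16

DEFAULT_LEN_MIN = 5
DEFAULT_LEN_MAX = 8
DEFAULT_K = 1000
DEFAULT_RESTARTS = 5000


@dataclass(frozen=True)
class CandidatePath:
    """An ordered simple path of distinct genes with its summed score."""

    genes: tuple[str, ...]
    score: float

    @property
    def gene_set(self) -> frozenset:
        return frozenset(self.genes)


@dataclass
class PathSet:
    """Top-K candidate paths, deduplicated by gene set, sorted by score."""

    paths: list[CandidatePath]
    capacity: int
    rng_seed: int | None = None

    def __len__(self) -> int:
        return len(self.paths)

    def __iter__(self):
        return iter(self.paths)

    def to_tsv(self, path) -> None:
        import pandas as pd

        rows = [
            {"rank": i + 1, "score": p.score, "genes": ",".join(p.genes)}
            for i, p in enumerate(self.paths)
        ]
        pd.DataFrame(rows, columns=["rank", "score", "genes"]).to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


def score_path(genes, scores: SeedScoreVector) -> float:
    """Sum of scores over the distinct genes of a path.

    Raises ``KeyError`` naming the first unscored gene.
    """
    if not genes:
        raise ValueError("path is empty")
    total = 0.0
    for g in set(genes):
        if g not in scores.scores:
            raise KeyError(f"gene {g!r} has no score")
        total += scores.scores[g]
    return total


def validate_path(
    path: CandidatePath,
    graph: nx.Graph,
    scores: SeedScoreVector,
    len_min: int,
    len_max: int,
) -> bool:
    """Check every candidate-path invariant; used by tests and assembly."""
    genes = path.genes
    if not (len_min <= len(genes) <= len_max):
        return False
    if len(set(genes)) != len(genes):
        return False
    if scores.seed not in genes:
        return False
    if not all(scores.is_eligible(g) for g in genes):
        return False
    if not all(graph.has_edge(a, b) for a, b in zip(genes, genes[1:])):
        return False
    return abs(path.score - score_path(genes, scores)) < 1e-9


def _exhaustive_paths(graph, scores, seed, len_min, len_max):
    """DFS over all simple paths through the seed of admissible length.

    The seed may sit anywhere along a pathway, so enumeration extends a
    simple path from both ends, starting from the seed alone.
    """
    results: dict[frozenset, CandidatePath] = {}
    eligible = {g for g in graph.nodes if scores.is_eligible(g)}

    def record(path_nodes):
        key = frozenset(path_nodes)
        if key not in results:
            results[key] = CandidatePath(tuple(path_nodes), score_path(path_nodes, scores))

    def extend(path_nodes):
        if len(path_nodes) >= len_min:
            record(path_nodes)
        if len(path_nodes) == len_max:
            return
        used = set(path_nodes)
        for nxt in graph.neighbors(path_nodes[-1]):
            if nxt in eligible and nxt not in used:
                extend(path_nodes + [nxt])
        for prv in graph.neighbors(path_nodes[0]):
            if prv in eligible and prv not in used:
                extend([prv] + path_nodes)

    if seed in eligible and seed in graph:
        extend([seed])
    return list(results.values())


def _randomized_paths(graph, scores, seed, len_min, len_max, n_restarts, rng):
    """Score-proportional random growth from the seed, restarted many times."""
    results: dict[frozenset, CandidatePath] = {}
    eligible = {g for g in graph.nodes if scores.is_eligible(g)}
    if seed not in eligible or seed not in graph:
        return []
    adjacency = {
        g: sorted(n for n in graph.neighbors(g) if n in eligible) for g in eligible
    }

    def record(path_nodes):
        key = frozenset(path_nodes)
        if key not in results:
            results[key] = CandidatePath(tuple(path_nodes), score_path(path_nodes, scores))

    for _ in range(n_restarts):
        path = [seed]
        used = {seed}
        while len(path) < len_max:
            # grow from either free end, weighting candidates by score
            frontier = [
                (end, nbr)
                for end in ({path[0], path[-1]} if len(path) > 1 else {seed})
                for nbr in adjacency[end]
                if nbr not in used
            ]
            if not frontier:
                break
            weights = np.array([scores.scores[nbr] for _, nbr in frontier])
            total = weights.sum()
            if total <= 0:
                idx = int(rng.integers(len(frontier)))
            else:
                idx = int(rng.choice(len(frontier), p=weights / total))
            end, nbr = frontier[idx]
            if end == path[-1]:
                path.append(nbr)
            else:
                path.insert(0, nbr)
            used.add(nbr)
            if len(path) >= len_min:
                record(path)
    return list(results.values())


def enumerate_paths(
    graph: nx.Graph,
    scores: SeedScoreVector,
    len_min: int = DEFAULT_LEN_MIN,
    len_max: int = DEFAULT_LEN_MAX,
    K: int = DEFAULT_K,
    n_restarts: int = DEFAULT_RESTARTS,
    rng_seed: int = 0,
    exhaustive_threshold: int = EXHAUSTIVE_NODE_THRESHOLD,
) -> PathSet:
    """Find up to K high-scoring simple seed pathways.

    Deterministic for a fixed ``rng_seed``.  An empty PathSet (e.g. the
    seed has no eligible neighbour, or the graph admits no path of
    admissible length) is not an error; it triggers module-discovery
    failure downstream.
    """
    if len_min < 2:
        raise ValueError("len_min must be >= 2")
    if len_max < len_min:
        raise ValueError("len_max must be >= len_min")
    if K < 1:
        raise ValueError("K must be >= 1")
    seed = scores.seed
    n_eligible = sum(1 for g in graph.nodes if scores.is_eligible(g))
    if n_eligible <= exhaustive_threshold:
        found = _exhaustive_paths(graph, scores, seed, len_min, len_max)
    else:
        rng = np.random.default_rng(rng_seed)
        found = _randomized_paths(graph, scores, seed, len_min, len_max, n_restarts, rng)
    found.sort(key=lambda p: (-p.score, p.genes))
    return PathSet(paths=found[:K], capacity=K, rng_seed=rng_seed)
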