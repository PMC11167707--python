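"""Molecular Complex Detection (MCODE) on a protein-interaction graph.

The algorithm has three stages:

1. **Vertex weighting.**  For each vertex v, take the closed neighbourhood
   N[v], find its highest k-core, and set
   ``weight(v) = k * density(k-core)`` with density = 2E / (n(n-1)).
   The weight of an isolated vertex is 0.
2. **Complex prediction.**  Starting from the highest-weight unvisited vertex
   whose degree meets ``degree_cutoff``, grow outward breadth-first, admitting
   a neighbour once per complex when its weight exceeds
   ``seed_weight * (1 - node_score_cutoff)`` and its depth from the seed is at
   most ``max_depth``.  Complexes are vertex-disjoint in assignment order.
3. **Post-processing.**  With ``haircut`` the complex is reduced to its
   2-core; complexes whose subgraph does not reach a ``k_core``-core (or that
   lose their seed) are discarded.  With ``fluff`` the immediate
   neighbourhood of each member is added when its neighbourhood density
   exceeds ``fluff_density``.

Ties are broken lexicographically by vertex id throughout, so results are
deterministic.  Complex score is density x size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "MCODEParams",
    "ComplexResult",
    "read_ppi_edges",
    "core_decomposition",
    "vertex_weight",
    "find_complexes",
    "seed_of",
]


@dataclass(frozen=True)
class MCODEParams:
    degree_cutoff: int = 5
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1

    def __post_init__(self) -> None:
        if self.degree_cutoff < 0:
            raise ValueError("degree_cutoff must be >= 0")
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValueError("node_score_cutoff is a fraction in [0, 1]")
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class ComplexResult:
    members: list[str]
    seed: str
    score: float
    rank: int = 0

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise ValueError("seed must be a complex member")


def read_ppi_edges(path, min_confidence: float = 0.0) -> nx.Graph:
    """Load an undirected simple graph from an edge-list TSV.

    Columns: two ids plus an optional confidence; edges below
    ``min_confidence`` are dropped at ingest.  Self-loops are discarded.
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    g = nx.Graph()
    for row in df.itertuples(index=False):
        a, b = str(row[0]), str(row[1])
        if a == b:
            continue
        conf = float(row[2]) if len(cols) > 2 and pd.notna(row[2]) else None
        if conf is not None and conf < min_confidence:
            continue
        g.add_edge(a, b, **({"confidence": conf} if conf is not None else {}))
    return g


# ---------------------------------------------------------------------------
# weighting
# ---------------------------------------------------------------------------

def core_decomposition(g: nx.Graph) -> dict[str, int]:
    """Standard k-core numbers of every vertex."""
    return dict(nx.core_number(g))


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * g.number_of_edges() / (n * (n - 1))


def vertex_weight(g: nx.Graph, v) -> float:
    """k * density of the highest k-core of the closed neighbourhood of v."""
    if v not in g:
        raise KeyError(v)
    nbhd = g.subgraph(list(g.neighbors(v)) + [v])
    if nbhd.number_of_edges() == 0:
        return 0.0
    cores = nx.core_number(nbhd)
    k = max(cores.values())
    core_sub = nbhd.subgraph([u for u, c in cores.items() if c >= k])
    return k * _density(core_sub)


# ---------------------------------------------------------------------------
# complex prediction
# ---------------------------------------------------------------------------

def find_complexes(g: nx.Graph, params: MCODEParams | None = None) -> list[ComplexResult]:
    """Run the full MCODE procedure; complexes sorted by descending score."""
    if params is None:
        params = MCODEParams()
    if g.number_of_nodes() == 0:
        return []
    if any(a == b for a, b in g.edges()):
        raise ValueError("self-loops are not allowed")

    weights = {v: vertex_weight(g, v) for v in g.nodes()}
    assigned: set = set()
    raw: list[tuple[str, list[str]]] = []

    # seeds in descending weight, ties lexicographic
    order = sorted(g.nodes(), key=lambda v: (-weights[v], str(v)))
    for seed in order:
        if seed in assigned or g.degree(seed) < params.degree_cutoff:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for v in frontier:
                for u in sorted(g.neighbors(v), key=str):
                    if u in members or u in assigned:
                        continue
                    if weights[u] > threshold:
                        members.add(u)
                        nxt.append(u)
            frontier = nxt
            depth += 1
        assigned |= members
        raw.append((seed, sorted(members, key=str)))

    results = []
    for seed, members in raw:
        sub = g.subgraph(members).copy()
        if params.haircut:
            sub = nx.k_core(sub, k=2)
        if params.fluff:
            extra = set()
            for v in list(sub.nodes()):
                nbhd = g.subgraph(list(g.neighbors(v)) + [v])
                if _density(nbhd) > params.fluff_density:
                    extra |= set(g.neighbors(v))
            sub = g.subgraph(set(sub.nodes()) | extra).copy()
        if sub.number_of_nodes() == 0 or seed not in sub:
            continue
        if max(nx.core_number(sub).values(), default=0) < params.k_core:
            continue
        score = _density(sub) * sub.number_of_nodes()
        results.append(ComplexResult(sorted(sub.nodes(), key=str), seed, score))

    results.sort(key=lambda c: (-c.score, str(c.seed)))
    for i, c in enumerate(results, start=1):
        c.rank = i
    return results


def seed_of(complex_result: ComplexResult) -> str:
    """The vertex the complex was grown from."""
    return complex_result.seed
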