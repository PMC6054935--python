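"""MCODE molecular-complex detection, implemented from its published definition.

The algorithm has three phases:

1. **Vertex weighting.**  Each vertex ``v`` is scored by its
   *core-clustering coefficient*: take the closed neighborhood of ``v``
   (``v`` plus its direct neighbors), find the highest k-core of that
   subgraph, and multiply that core's ``k`` by its edge density
   ``2m / (n(n-1))``.  A degree-0 vertex has weight 0.

2. **Complex prediction.**  Repeatedly seed from the highest-weight
   unvisited vertex and grow outward, admitting unvisited neighbors whose
   weight is at least ``(1 - node_score_cutoff)`` times the seed weight;
   admitted vertices are marked visited, so complexes are vertex-disjoint.

3. **Post-processing.**  With *haircut* on, members with exactly one
   intra-complex edge are removed (iterated to a fixpoint).  Complexes with
   fewer than two members, or lacking an internal k-core at ``kcore_filter``,
   are discarded.  Survivors are scored by density × size and labeled
   M1, M2, … by non-increasing score, ties broken by the lexicographically
   smallest member tuple.

All tie-breaks (seed order, growth order, labeling) are lexicographic on
vertex ids, so results are independent of input edge order.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from psanet.errors import ParameterError


@dataclass(frozen=True)
class McodeParams:
    node_score_cutoff: float = 0.2
    kcore_filter: int = 3
    haircut: bool = True
    fluff: bool = False

    def validate(self) -> "McodeParams":
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ParameterError("node_score_cutoff must be in [0, 1]")
        if self.kcore_filter < 0:
            raise ParameterError("kcore_filter must be >= 0")
        if self.fluff:
            raise ParameterError("fluff (overlapping complexes) is not supported")
        return self


@dataclass(frozen=True)
class ModuleRecord:
    """A detected complex: members, density, score and rank label."""

    label: str
    members: frozenset[str]
    density: float
    score: float
    contains_kcore_k: bool


def _check_simple(graph: nx.Graph) -> None:
    if graph.is_directed() or graph.is_multigraph():
        raise ParameterError("MCODE requires a simple undirected graph")


def core_number(graph: nx.Graph) -> dict:
    """Per-vertex core number (largest k with the vertex in a k-core)."""
    _check_simple(graph)
    g = graph
    if nx.number_of_selfloops(g):
        g = g.copy()
        g.remove_edges_from(nx.selfloop_edges(g))
    return dict(nx.core_number(g))


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def vertex_weights(graph: nx.Graph) -> dict:
    """MCODE vertex weights (core-clustering coefficient × highest-core k)."""
    _check_simple(graph)
    weights = {}
    for v in graph.nodes:
        nbhd = set(graph.neighbors(v)) | {v}
        if len(nbhd) < 2:
            weights[v] = 0.0
            continue
        sub = graph.subgraph(nbhd)
        cores = core_number(sub)
        k_max = max(cores.values())
        if k_max == 0:
            weights[v] = 0.0
            continue
        core_nodes = [u for u, c in cores.items() if c >= k_max]
        weights[v] = k_max * _density(sub.subgraph(core_nodes))
    return weights


def module_score(members, graph: nx.Graph) -> float:
    """MCODE complex score: induced-subgraph density × member count."""
    members = set(members)
    sub = graph.subgraph(members)
    return _density(sub) * len(members)


def _grow(graph, seed, weights, threshold, visited):
    members = {seed}
    visited.add(seed)
    stack = [seed]
    while stack:
        v = stack.pop()
        for u in sorted(graph.neighbors(v), key=str):
            if u not in visited and weights[u] >= threshold:
                visited.add(u)
                members.add(u)
                stack.append(u)
    return members


def _haircut(members: set, graph: nx.Graph) -> set:
    # iteratively drop members with exactly one intra-complex edge
    while True:
        sub = graph.subgraph(members)
        singly = {v for v in members if sub.degree(v) == 1}
        if not singly:
            return members
        members = members - singly


def find_complexes(
    graph: nx.Graph, params: McodeParams | None = None
) -> list[ModuleRecord]:
    """Detect, post-process, score and label MCODE complexes."""
    _check_simple(graph)
    params = (params or McodeParams()).validate()

    weights = vertex_weights(graph)
    order = sorted(graph.nodes, key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    candidates: list[set] = []
    for seed in order:
        if seed in visited:
            continue
        threshold = (1.0 - params.node_score_cutoff) * weights[seed]
        candidates.append(_grow(graph, seed, weights, threshold, visited))

    records = []
    for members in candidates:
        if params.haircut:
            members = _haircut(set(members), graph)
        if len(members) < 2:
            continue
        sub = graph.subgraph(members)
        if max(core_number(sub).values()) < params.kcore_filter:
            continue
        density = _density(sub)
        records.append(
            ModuleRecord(
                label="",
                members=frozenset(members),
                density=density,
                score=density * len(members),
                contains_kcore_k=True,
            )
        )

    records.sort(key=lambda r: (-r.score, tuple(sorted(r.members))))
    return [
        ModuleRecord(
            label=f"M{i + 1}",
            members=r.members,
            density=r.density,
            score=r.score,
            contains_kcore_k=r.contains_kcore_k,
        )
        for i, r in enumerate(records)
    ]
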