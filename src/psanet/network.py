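"""Tri-layer network construction, edge enrichment and lncRNA connectivity.

The gene scaffold is the PPI subnetwork induced on a gene set of interest;
regulatory edges (lncRNA→gene, lncRNA→miRNA, miRNA→gene) are attached on top
without altering the scaffold.  A lncRNA's connectivity is the number of
distinct scaffold genes it reaches directly (lncRNA→gene) or through exactly
one miRNA hop (lncRNA→miRNA→gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import stats

from psanet.containers import (
    LNC_GENE,
    LNC_MIRNA,
    MIRNA_GENE,
    Edge,
    InteractionCatalog,
)
from psanet.errors import ConsistencyError, ParameterError
from psanet.targets import SelectionResult


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    n_connected_nodes: int
    enrichment_p: float | None = None


@dataclass
class TriLayerNetwork:
    """PPI scaffold over genes plus typed regulatory edges."""

    gene_vertices: frozenset[str]
    ppi: nx.Graph
    lnc_gene_edges: frozenset[Edge] = frozenset()
    lnc_mirna_edges: frozenset[Edge] = frozenset()
    mirna_gene_edges: frozenset[Edge] = frozenset()

    @property
    def isolated_genes(self) -> frozenset[str]:
        return frozenset(v for v in self.gene_vertices if self.ppi.degree(v) == 0)

    def ppi_degree(self, gene: str) -> int:
        return self.ppi.degree(gene) if gene in self.ppi else 0


@dataclass(frozen=True)
class ConnectivityProfile:
    """Direct and one-miRNA-hop gene targets of one lncRNA."""

    lncrna_id: str
    direct_targets: frozenset[str]
    indirect_targets: frozenset[str]
    connectivity_score: int


def build_ppi_subnetwork(
    genes, catalog: InteractionCatalog
) -> tuple[TriLayerNetwork, NetworkStats]:
    """Induce the catalog's PPI graph on ``genes``.

    Genes without any retained interaction stay in the network as isolated
    (unconnected) vertices and are counted in ``n_nodes`` but not in
    ``n_connected_nodes``.
    """
    genes = frozenset(str(g).strip() for g in genes)
    full = catalog.ppi_graph()
    sub = nx.Graph()
    sub.add_nodes_from(genes)
    sub.add_edges_from(
        (a, b) for a, b in full.edges if a in genes and b in genes
    )
    net = TriLayerNetwork(gene_vertices=genes, ppi=sub)
    stats_ = NetworkStats(
        n_nodes=len(genes),
        n_edges=sub.number_of_edges(),
        n_connected_nodes=sum(1 for v in genes if sub.degree(v) > 0),
    )
    return net, stats_


def ppi_enrichment_pvalue(
    network: TriLayerNetwork,
    catalog: InteractionCatalog,
    method: str = "permutation",
    n_perm: int = 999,
    seed: int | None = None,
) -> float:
    """Probability of seeing at least the observed number of PPI edges.

    The null model draws uniform random gene sets of the same size from the
    catalog's gene universe.  ``permutation`` computes the add-one permutation
    p-value over ``n_perm`` draws; ``poisson`` is a fast approximation using
    the upper-tail Poisson probability at the expected edge count under
    uniform vertex sampling.
    """
    universe = sorted(catalog.gene_universe())
    if not network.gene_vertices <= set(universe):
        raise ConsistencyError("network genes fall outside the catalog universe")
    n = len(network.gene_vertices)
    N = len(universe)
    observed = network.ppi.number_of_edges()
    if n < 2:
        return 1.0

    full = catalog.ppi_graph()
    if method == "poisson":
        m_total = full.number_of_edges()
        mu = m_total * (n * (n - 1)) / (N * (N - 1))
        return float(stats.poisson.sf(observed - 1, mu))
    if method != "permutation":
        raise ParameterError("method must be 'permutation' or 'poisson'")

    rng = np.random.default_rng(seed)
    adj = {v: set(full.neighbors(v)) for v in full.nodes}
    universe_arr = np.array(universe)
    hits = 0
    for _ in range(n_perm):
        draw = universe_arr[rng.choice(N, size=n, replace=False)]
        picked = set(draw.tolist())
        m = 0
        for v in picked:
            nbrs = adj.get(v)
            if nbrs:
                m += len(nbrs & picked)
        m //= 2
        if m >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def augment_with_regulatory_edges(
    network: TriLayerNetwork, selection: SelectionResult
) -> TriLayerNetwork:
    """Attach the selection's regulatory edges; the PPI layer is unchanged."""
    return replace(
        network,
        lnc_gene_edges=frozenset(selection.lnc_gene_edges),
        lnc_mirna_edges=frozenset(selection.lnc_mirna_edges),
        mirna_gene_edges=frozenset(selection.mirna_gene_edges),
    )


def lncrna_connectivity(network: TriLayerNetwork) -> list[ConnectivityProfile]:
    """Per-lncRNA direct and one-miRNA-hop targets within the gene scaffold.

    ``connectivity_score`` counts distinct scaffold genes reached either way.
    Profiles are returned sorted by descending score, ties by id.
    """
    direct: dict[str, set[str]] = {}
    for e in network.lnc_gene_edges:
        direct.setdefault(e.source, set()).add(e.target)
    lnc_mirs: dict[str, set[str]] = {}
    for e in network.lnc_mirna_edges:
        lnc_mirs.setdefault(e.source, set()).add(e.target)
    mir_genes: dict[str, set[str]] = {}
    for e in network.mirna_gene_edges:
        mir_genes.setdefault(e.source, set()).add(e.target)

    profiles = []
    for lnc in sorted(set(direct) | set(lnc_mirs)):
        d = frozenset(direct.get(lnc, set()))
        ind: set[str] = set()
        for mir in lnc_mirs.get(lnc, set()):
            ind |= mir_genes.get(mir, set())
        score = len((d | ind) & network.gene_vertices)
        profiles.append(
            ConnectivityProfile(
                lncrna_id=lnc,
                direct_targets=d,
                indirect_targets=frozenset(ind),
                connectivity_score=score,
            )
        )
    profiles.sort(key=lambda p: (-p.connectivity_score, p.lncrna_id))
    return profiles


def rank_lncrnas(profiles, top_k: int = 7) -> list[str]:
    """Top-k lncRNA ids by descending connectivity, ties lexicographic."""
    ordered = sorted(profiles, key=lambda p: (-p.connectivity_score, p.lncrna_id))
    return [p.lncrna_id for p in ordered[:top_k]]
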