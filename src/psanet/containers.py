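"""Shared in-memory containers: expression cohorts and interaction catalogs.

Transcript classes use three fixed labels (``gene``, ``lncRNA``, ``miRNA``);
interaction types distinguish the three regulatory layers plus undirected
protein–protein interactions (``ppi``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx
import pandas as pd

from psanet.errors import ConsistencyError

GENE = "gene"
LNCRNA = "lncRNA"
MIRNA = "miRNA"
TRANSCRIPT_CLASSES = (GENE, LNCRNA, MIRNA)

LNC_GENE = "lnc_gene"
LNC_MIRNA = "lnc_mirna"
MIRNA_GENE = "mirna_gene"
PPI = "ppi"
INTERACTION_TYPES = (LNC_GENE, LNC_MIRNA, MIRNA_GENE, PPI)

#: expected (source_class, target_class) per interaction type
_EDGE_CLASSES = {
    LNC_GENE: (LNCRNA, GENE),
    LNC_MIRNA: (LNCRNA, MIRNA),
    MIRNA_GENE: (MIRNA, GENE),
    PPI: (GENE, GENE),
}

CASE = "case"
CONTROL = "control"


def normalize_id(identifier: str) -> str:
    """Strip surrounding whitespace from an identifier."""
    return str(identifier).strip()


def match_key(identifier: str) -> str:
    """Case-insensitive matching key (whitespace-stripped, casefolded)."""
    return normalize_id(identifier).casefold()


@dataclass
class ExpressionMatrix:
    """Linear-scale expression values with transcript and sample labels.

    Parameters
    ----------
    values
        transcripts × samples DataFrame of positive linear-scale intensities.
    transcript_class
        Series indexed like ``values`` rows with values in
        ``{"gene", "lncRNA", "miRNA"}``.
    sample_group
        Series indexed like ``values`` columns with values in
        ``{"case", "control"}``.
    """

    values: pd.DataFrame
    transcript_class: pd.Series
    sample_group: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.transcript_class.index):
            raise ConsistencyError("transcript_class index must match value rows")
        if not self.values.columns.equals(self.sample_group.index):
            raise ConsistencyError("sample_group index must match value columns")
        bad = set(self.transcript_class.unique()) - set(TRANSCRIPT_CLASSES)
        if bad:
            raise ConsistencyError(f"unknown transcript classes: {sorted(bad)}")
        bad = set(self.sample_group.unique()) - {CASE, CONTROL}
        if bad:
            raise ConsistencyError(f"unknown sample groups: {sorted(bad)}")

    @property
    def case_samples(self) -> list[str]:
        return list(self.sample_group.index[self.sample_group == CASE])

    @property
    def control_samples(self) -> list[str]:
        return list(self.sample_group.index[self.sample_group == CONTROL])

    def ids_of_class(self, transcript_class: str) -> list[str]:
        mask = self.transcript_class == transcript_class
        return list(self.transcript_class.index[mask])


@dataclass(frozen=True, order=True)
class Edge:
    """A typed interaction-catalog edge."""

    source: str
    source_class: str
    target: str
    target_class: str
    etype: str

    def validate(self) -> "Edge":
        if self.etype not in _EDGE_CLASSES:
            raise ConsistencyError(f"unknown interaction type {self.etype!r}")
        want = _EDGE_CLASSES[self.etype]
        if (self.source_class, self.target_class) != want:
            raise ConsistencyError(
                f"{self.etype} edge requires classes {want}, got "
                f"({self.source_class}, {self.target_class})"
            )
        if match_key(self.source) == match_key(self.target):
            raise ConsistencyError(f"self-edge {self.source!r}")
        return self


def _canonical(edge: Edge) -> Edge:
    """Normalize ids; store PPI edges with sorted endpoints."""
    src, tgt = normalize_id(edge.source), normalize_id(edge.target)
    if edge.etype == PPI and tgt < src:
        src, tgt = tgt, src
    return Edge(src, edge.source_class, tgt, edge.target_class, edge.etype)


class InteractionCatalog:
    """A deduplicated store of typed edges across the molecular layers.

    Edges are validated on construction: no self-edges, class labels
    consistent with the interaction type, PPI edges stored with
    lexicographically ordered endpoints.
    """

    def __init__(self, edges: Iterable[Edge] = ()):
        self._edges: frozenset[Edge] = frozenset(
            _canonical(e.validate()) for e in edges
        )

    @property
    def edges(self) -> frozenset[Edge]:
        return self._edges

    def __len__(self) -> int:
        return len(self._edges)

    def __iter__(self) -> Iterator[Edge]:
        return iter(sorted(self._edges))

    def __eq__(self, other: object) -> bool:
        return isinstance(other, InteractionCatalog) and self._edges == other._edges

    def edges_of_type(self, etype: str) -> frozenset[Edge]:
        return frozenset(e for e in self._edges if e.etype == etype)

    def merge(self, other: "InteractionCatalog") -> "InteractionCatalog":
        cat = InteractionCatalog()
        cat._edges = self._edges | other._edges
        return cat

    def sources_of_type(self, etype: str) -> frozenset[str]:
        return frozenset(e.source for e in self._edges if e.etype == etype)

    def ppi_graph(self) -> nx.Graph:
        """Undirected simple graph over the catalog's PPI edges."""
        g = nx.Graph()
        g.add_edges_from(
            (e.source, e.target) for e in self._edges if e.etype == PPI
        )
        return g

    def gene_universe(self) -> frozenset[str]:
        """All gene ids appearing at either end of any edge."""
        out = set()
        for e in self._edges:
            if e.source_class == GENE:
                out.add(e.source)
            if e.target_class == GENE:
                out.add(e.target)
        return frozenset(out)
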