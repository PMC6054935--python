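"""Target-selection cascade over the interaction catalog.

The cascade mirrors a common integrative design: (1) keep modulated lncRNAs
that have at least one annotated target in the catalog; (2) restrict their
gene / miRNA targets to the modulated gene set and to an externally supplied
modulated-miRNA list; (3) expand the retained miRNAs to their catalog gene
targets, again restricted to modulated genes.  Identifier matching is
case-insensitive after whitespace stripping; no alias resolution is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from psanet.containers import (
    LNC_GENE,
    LNC_MIRNA,
    MIRNA_GENE,
    Edge,
    InteractionCatalog,
    match_key,
)


@dataclass
class SelectionResult:
    """Outcome of the cascade: retained lncRNAs and edges, per-stage counts."""

    selected_lncrnas: frozenset[str] = frozenset()
    lnc_gene_edges: frozenset[Edge] = frozenset()
    lnc_mirna_edges: frozenset[Edge] = frozenset()
    mirna_gene_edges: frozenset[Edge] = frozenset()
    summary: dict[str, int] = field(default_factory=dict)

    @property
    def selected_mirnas(self) -> frozenset[str]:
        """Distinct miRNA identifiers among retained lncRNA→miRNA edges."""
        return frozenset(e.target for e in self.lnc_mirna_edges)

    @property
    def target_gene_universe(self) -> frozenset[str]:
        """Genes at the receiving end of any retained regulatory edge."""
        return frozenset(e.target for e in self.lnc_gene_edges) | frozenset(
            e.target for e in self.mirna_gene_edges
        )

    def recount(self) -> "SelectionResult":
        self.summary = {
            "selected_lncrnas": len(self.selected_lncrnas),
            "lnc_gene_edges": len(self.lnc_gene_edges),
            "lnc_mirna_edges": len(self.lnc_mirna_edges),
            "mirna_gene_edges": len(self.mirna_gene_edges),
            "selected_mirnas": len(self.selected_mirnas),
            "target_genes": len(self.target_gene_universe),
        }
        return self


def _keyset(ids: Iterable[str]) -> frozenset[str]:
    return frozenset(match_key(i) for i in ids)


def select_annotated_lncrnas(
    modulated_lncrnas: Iterable[str], catalog: InteractionCatalog
) -> frozenset[str]:
    """Modulated lncRNAs with at least one annotated target in the catalog.

    Returns identifiers as given in ``modulated_lncrnas``.
    """
    annotated = _keyset(
        e.source for e in catalog.edges if e.etype in (LNC_GENE, LNC_MIRNA)
    )
    return frozenset(
        lnc for lnc in modulated_lncrnas if match_key(lnc) in annotated
    )


def restrict_targets(
    lncrnas: Iterable[str],
    catalog: InteractionCatalog,
    modulated_genes: Iterable[str],
    modulated_mirnas: Iterable[str],
) -> SelectionResult:
    """Keep only regulatory edges whose targets show evidence of modulation.

    lncRNA→gene edges survive iff the gene is modulated; lncRNA→miRNA edges
    iff the miRNA is in the modulated-miRNA list; lncRNAs retaining no edge
    are dropped from the selection.
    """
    lnc_keys = _keyset(lncrnas)
    gene_keys = _keyset(modulated_genes)
    mir_keys = _keyset(modulated_mirnas)

    lnc_gene = frozenset(
        e
        for e in catalog.edges_of_type(LNC_GENE)
        if match_key(e.source) in lnc_keys and match_key(e.target) in gene_keys
    )
    lnc_mir = frozenset(
        e
        for e in catalog.edges_of_type(LNC_MIRNA)
        if match_key(e.source) in lnc_keys and match_key(e.target) in mir_keys
    )
    retained_sources = _keyset(e.source for e in lnc_gene) | _keyset(
        e.source for e in lnc_mir
    )
    selected = frozenset(
        lnc for lnc in lncrnas if match_key(lnc) in retained_sources
    )
    return SelectionResult(
        selected_lncrnas=selected,
        lnc_gene_edges=lnc_gene,
        lnc_mirna_edges=lnc_mir,
    ).recount()


def expand_mirna_targets(
    mirnas: Iterable[str],
    catalog: InteractionCatalog,
    modulated_genes: Iterable[str],
) -> frozenset[Edge]:
    """miRNA→gene catalog edges from the given miRNAs into modulated genes."""
    mir_keys = _keyset(mirnas)
    gene_keys = _keyset(modulated_genes)
    return frozenset(
        e
        for e in catalog.edges_of_type(MIRNA_GENE)
        if match_key(e.source) in mir_keys and match_key(e.target) in gene_keys
    )


def select_targets(
    modulated_lncrnas: Iterable[str],
    modulated_genes: Iterable[str],
    modulated_mirnas: Iterable[str],
    catalog: InteractionCatalog,
) -> SelectionResult:
    """Run the full cascade and return the combined selection.

    ``summary`` additionally records ``annotated_lncrnas``, the size of the
    selection after the annotation stage alone (before target restriction).
    """
    modulated_lncrnas = list(modulated_lncrnas)
    annotated = select_annotated_lncrnas(modulated_lncrnas, catalog)
    result = restrict_targets(annotated, catalog, modulated_genes, modulated_mirnas)
    result.mirna_gene_edges = expand_mirna_targets(
        result.selected_mirnas, catalog, modulated_genes
    )
    result.recount()
    result.summary["modulated_lncrnas"] = len(set(modulated_lncrnas))
    result.summary["annotated_lncrnas"] = len(annotated)
    return result
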