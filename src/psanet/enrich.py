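"""Hypergeometric module enrichment and the lncRNA-by-module targeting matrix.

Enrichment of a module (gene set of size ``n`` within a background of size
``N``) against an annotation term (``K`` background genes annotated) is the
upper-tail hypergeometric probability of the observed overlap ``k``:

    p = sum_{j=k}^{min(K, n)} C(K, j) C(N-K, n-j) / C(N, n)

Terms are flat gene sets (GMT-style); no ontology-graph propagation is
applied.  Significance uses the raw p-value at the configured threshold; a
Benjamini–Hochberg-adjusted column is always emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from scipy import stats
from statsmodels.stats.multitest import multipletests

from psanet.errors import ConsistencyError, ParameterError
from psanet.mcode import ModuleRecord
from psanet.network import TriLayerNetwork
from psanet.targets import SelectionResult

NONE, DIRECT, INDIRECT, BOTH = "none", "direct", "indirect", "both"


@dataclass(frozen=True)
class EnrichmentRecord:
    module_label: str
    term_id: str
    N: int
    K: int
    n: int
    k: int
    p_hg: float
    p_bh: float
    significant: bool


def hypergeometric_enrichment(
    module: Iterable[str],
    terms: Mapping[str, Iterable[str]],
    background: Iterable[str],
    threshold: float = 0.05,
    module_label: str = "",
) -> list[EnrichmentRecord]:
    """Score one module against every annotation term.

    ``module`` must be a subset of ``background``; each term is intersected
    with the background before counting.  Records are sorted by ascending
    p-value, ties by term id.  An empty module yields an empty list.
    """
    background = frozenset(background)
    if not background:
        raise ParameterError("background universe is empty")
    module = frozenset(module)
    if not module <= background:
        raise ConsistencyError("module must be a subset of the background")
    if not module:
        return []
    if not 0.0 < threshold <= 1.0:
        raise ParameterError("threshold must be in (0, 1]")

    N, n = len(background), len(module)
    rows = []
    for term_id in sorted(terms):
        term = frozenset(terms[term_id]) & background
        K = len(term)
        k = len(term & module)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((term_id, K, k, min(p, 1.0)))

    p_bh = multipletests([r[3] for r in rows], method="fdr_bh")[1]
    records = [
        EnrichmentRecord(
            module_label=module_label,
            term_id=term_id,
            N=N,
            K=K,
            n=n,
            k=k,
            p_hg=p,
            p_bh=float(bh),
            significant=p <= threshold,
        )
        for (term_id, K, k, p), bh in zip(rows, p_bh)
    ]
    records.sort(key=lambda r: (r.p_hg, r.term_id))
    return records


@dataclass
class TargetingMatrix:
    """lncRNA × module targeting: ``none``, ``direct``, ``indirect`` or ``both``."""

    cells: dict[tuple[str, str], str] = field(default_factory=dict)
    lncrnas: list[str] = field(default_factory=list)
    module_labels: list[str] = field(default_factory=list)

    def cell(self, lncrna: str, module_label: str) -> str:
        return self.cells.get((lncrna, module_label), NONE)

    def lncrna_counts(self) -> dict[str, int]:
        """Number of modules each lncRNA targets (cells other than none)."""
        return {
            lnc: sum(
                1 for m in self.module_labels if self.cell(lnc, m) != NONE
            )
            for lnc in self.lncrnas
        }

    def targeted_modules(self) -> list[str]:
        return [
            m
            for m in self.module_labels
            if any(self.cell(lnc, m) != NONE for lnc in self.lncrnas)
        ]


def module_targeting_matrix(
    modules: Iterable[ModuleRecord],
    selection: SelectionResult,
    network: TriLayerNetwork,
) -> TargetingMatrix:
    """Which modules each selected lncRNA targets, directly or via one miRNA.

    A cell is ``direct`` when some lncRNA→gene edge lands in the module,
    ``indirect`` when some lncRNA→miRNA→gene two-step path does, ``both``
    when both hold.
    """
    modules = list(modules)
    direct: dict[str, set[str]] = {}
    for e in selection.lnc_gene_edges:
        direct.setdefault(e.source, set()).add(e.target)
    lnc_mirs: dict[str, set[str]] = {}
    for e in selection.lnc_mirna_edges:
        lnc_mirs.setdefault(e.source, set()).add(e.target)
    mir_genes: dict[str, set[str]] = {}
    for e in selection.mirna_gene_edges:
        mir_genes.setdefault(e.source, set()).add(e.target)

    matrix = TargetingMatrix(
        lncrnas=sorted(selection.selected_lncrnas),
        module_labels=[m.label for m in modules],
    )
    for lnc in matrix.lncrnas:
        d = direct.get(lnc, set())
        ind: set[str] = set()
        for mir in lnc_mirs.get(lnc, set()):
            ind |= mir_genes.get(mir, set())
        for mod in modules:
            has_d = bool(d & mod.members)
            has_i = bool(ind & mod.members)
            if has_d and has_i:
                matrix.cells[(lnc, mod.label)] = BOTH
            elif has_d:
                matrix.cells[(lnc, mod.label)] = DIRECT
            elif has_i:
                matrix.cells[(lnc, mod.label)] = INDIRECT
    return matrix


def targeted_module_summary(
    matrix: TargetingMatrix,
) -> tuple[dict[str, int], float]:
    """Per-lncRNA targeted-module counts and the fraction of modules targeted."""
    counts = matrix.lncrna_counts()
    total = len(matrix.module_labels)
    fraction = len(matrix.targeted_modules()) / total if total else 0.0
    return counts, fraction
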