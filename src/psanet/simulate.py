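"""Synthetic cohorts, interaction catalogs, PPI graphs and annotation sets.

Every generator plants a known ground truth (recorded in a
:class:`TruthManifest`) so downstream stages — differential filtering, the
target-selection cascade, network construction, complex detection and
enrichment — can be validated end to end without external databases.

The cohort emulates a small two-group PBMC microarray study: ~10 case and
~10 control samples, log-normal intensities (Gaussian on the log2 scale),
and planted differential-expression effects of a fixed linear fold change
with random direction per transcript.  The interaction catalog plants a few
"master regulator" lncRNAs whose targets concentrate on differentially
expressed miRNAs and on genes inside planted PPI modules; the PPI graph is a
planted-partition graph (dense within modules at ``p_in``, sparse background
at ``p_out``); one annotation term per planted module draws most of its
members from that module.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from psanet.containers import (
    CASE,
    CONTROL,
    GENE,
    LNCRNA,
    LNC_GENE,
    LNC_MIRNA,
    MIRNA,
    MIRNA_GENE,
    Edge,
    ExpressionMatrix,
    InteractionCatalog,
)
from psanet.errors import ConsistencyError, ParameterError


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the synthetic study.

    Counts size the cohort; ``effect_fold`` is the planted linear fold change
    (case vs control) and ``noise_sigma`` the per-measurement standard
    deviation of log2 intensity.  ``p_in``/``p_out`` are the within/between
    module PPI edge probabilities of the planted-partition graph.
    """

    n_genes: int = 400
    n_lncrnas: int = 80
    n_mirnas: int = 40
    n_case: int = 10
    n_control: int = 10
    frac_de_genes: float = 0.25
    frac_de_lncrnas: float = 0.25
    frac_de_mirnas: float = 0.30
    effect_fold: float = 2.5
    noise_sigma: float = 0.5
    n_regulator_lncrnas: int = 5
    n_planted_modules: int = 4
    module_size: int = 12
    p_in: float = 0.9
    p_out: float = 0.02
    n_terms: int = 20
    term_size_min: int = 8
    term_size_max: int = 25
    term_random_frac: float = 0.25
    regulator_gene_out: int = 12
    regulator_mirna_out: int = 3
    mirna_gene_out: int = 8
    background_edge_rate: float = 1.0
    seed: int = 0

    def validate(self) -> "SimulationParams":
        for name in ("n_genes", "n_lncrnas", "n_mirnas", "n_regulator_lncrnas",
                     "n_planted_modules", "module_size", "n_terms"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_genes + self.n_lncrnas + self.n_mirnas <= 0:
            raise ParameterError("cohort must contain at least one transcript")
        if self.n_case < 2 or self.n_control < 2:
            raise ParameterError("need at least 2 samples per group")
        for name in ("frac_de_genes", "frac_de_lncrnas", "frac_de_mirnas",
                     "term_random_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        for name in ("p_in", "p_out"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.p_in <= self.p_out:
            raise ParameterError("p_in must exceed p_out")
        if self.effect_fold < 1.0:
            raise ParameterError("effect_fold must be >= 1 (use 1 for no effect)")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        n_de_genes = round(self.frac_de_genes * self.n_genes)
        if self.n_planted_modules * self.module_size > n_de_genes:
            raise ParameterError(
                "planted modules need "
                f"{self.n_planted_modules * self.module_size} DE genes but only "
                f"{n_de_genes} are planted"
            )
        if self.n_regulator_lncrnas > round(self.frac_de_lncrnas * self.n_lncrnas):
            raise ParameterError("more regulator lncRNAs than planted DE lncRNAs")
        if not 1 <= self.term_size_min <= self.term_size_max:
            raise ParameterError("term sizes must satisfy 1 <= min <= max")
        return self


@dataclass
class TruthManifest:
    """Planted ground truth of one synthetic study."""

    de_genes: frozenset[str] = frozenset()
    de_lncrnas: frozenset[str] = frozenset()
    de_mirnas: frozenset[str] = frozenset()
    de_sign: dict[str, int] = field(default_factory=dict)
    regulator_lncrnas: frozenset[str] = frozenset()
    planted_modules: list[frozenset[str]] = field(default_factory=list)
    enriched_term_per_module: dict[str, int] = field(default_factory=dict)

    def de_of_class(self, transcript_class: str) -> frozenset[str]:
        return {
            GENE: self.de_genes,
            LNCRNA: self.de_lncrnas,
            MIRNA: self.de_mirnas,
        }[transcript_class]

    def validate(self) -> "TruthManifest":
        if not self.regulator_lncrnas <= self.de_lncrnas:
            raise ConsistencyError("regulator lncRNAs must be planted DE lncRNAs")
        seen: set[str] = set()
        for mod in self.planted_modules:
            if seen & mod:
                raise ConsistencyError("planted modules must be pairwise disjoint")
            seen |= mod
        de_all = self.de_genes | self.de_lncrnas | self.de_mirnas
        if set(self.de_sign) != de_all:
            raise ConsistencyError("de_sign must cover exactly the DE transcripts")
        return self

    def to_json(self) -> str:
        payload = {
            "de_genes": sorted(self.de_genes),
            "de_lncrnas": sorted(self.de_lncrnas),
            "de_mirnas": sorted(self.de_mirnas),
            "de_sign": dict(sorted(self.de_sign.items())),
            "regulator_lncrnas": sorted(self.regulator_lncrnas),
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "enriched_term_per_module": dict(
                sorted(self.enriched_term_per_module.items())
            ),
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthManifest":
        d = json.loads(text)
        return cls(
            de_genes=frozenset(d["de_genes"]),
            de_lncrnas=frozenset(d["de_lncrnas"]),
            de_mirnas=frozenset(d["de_mirnas"]),
            de_sign={k: int(v) for k, v in d["de_sign"].items()},
            regulator_lncrnas=frozenset(d["regulator_lncrnas"]),
            planted_modules=[frozenset(m) for m in d["planted_modules"]],
            enriched_term_per_module={
                k: int(v) for k, v in d["enriched_term_per_module"].items()
            },
        )


def gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def lncrna_ids(n: int) -> list[str]:
    return [f"LNC{i:04d}" for i in range(1, n + 1)]


def mirna_ids(n: int) -> list[str]:
    return [f"MIR{i:04d}" for i in range(1, n + 1)]


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    # independent streams per generator so e.g. regenerating the catalog
    # does not perturb the cohort
    return np.random.default_rng([params.seed, stream])


def generate_cohort(params: SimulationParams) -> tuple[ExpressionMatrix, TruthManifest]:
    """Simulate the two-group expression matrix and plant the ground truth.

    Expression is Gaussian on the log2 scale around a transcript-specific
    baseline; planted DE transcripts have their case-group mean shifted by
    ``±log2(effect_fold)`` with the sign drawn per transcript and recorded in
    the manifest.  The returned matrix is on the linear scale.
    """
    params.validate()
    rng = _rng(params, 0)

    ids_by_class = [
        (GENE, gene_ids(params.n_genes)),
        (LNCRNA, lncrna_ids(params.n_lncrnas)),
        (MIRNA, mirna_ids(params.n_mirnas)),
    ]
    all_ids = [i for _, ids in ids_by_class for i in ids]
    classes = [c for c, ids in ids_by_class for _ in ids]

    samples = [f"case{i:02d}" for i in range(1, params.n_case + 1)] + [
        f"ctrl{i:02d}" for i in range(1, params.n_control + 1)
    ]
    groups = [CASE] * params.n_case + [CONTROL] * params.n_control

    frac = {GENE: params.frac_de_genes, LNCRNA: params.frac_de_lncrnas,
            MIRNA: params.frac_de_mirnas}
    de_sets: dict[str, frozenset[str]] = {}
    de_sign: dict[str, int] = {}
    for cls, ids in ids_by_class:
        n_de = round(frac[cls] * len(ids))
        chosen = rng.choice(len(ids), size=n_de, replace=False) if n_de else []
        de = frozenset(ids[i] for i in np.sort(chosen))
        de_sets[cls] = de
        for t in sorted(de):
            de_sign[t] = int(rng.choice([-1, 1]))

    # planted PPI modules: disjoint subsets of the planted DE genes
    de_genes_sorted = sorted(de_sets[GENE])
    perm = rng.permutation(len(de_genes_sorted))
    modules: list[frozenset[str]] = []
    for m in range(params.n_planted_modules):
        lo = m * params.module_size
        idx = perm[lo: lo + params.module_size]
        modules.append(frozenset(de_genes_sorted[i] for i in idx))

    # master-regulator lncRNAs among the planted DE lncRNAs
    de_lnc_sorted = sorted(de_sets[LNCRNA])
    reg_idx = rng.choice(
        len(de_lnc_sorted), size=params.n_regulator_lncrnas, replace=False
    ) if params.n_regulator_lncrnas else []
    regulators = frozenset(de_lnc_sorted[i] for i in np.sort(reg_idx))

    n_tx, n_s = len(all_ids), len(samples)
    baseline = rng.uniform(4.0, 10.0, size=n_tx)
    shift = np.zeros(n_tx)
    log2_fold = math.log2(params.effect_fold)
    for i, t in enumerate(all_ids):
        if t in de_sign:
            shift[i] = de_sign[t] * log2_fold
    mean = np.tile(baseline[:, None], (1, n_s))
    mean[:, : params.n_case] += shift[:, None]
    log2_values = mean + rng.normal(0.0, params.noise_sigma, size=(n_tx, n_s))
    values = pd.DataFrame(
        np.exp2(log2_values), index=pd.Index(all_ids, name="transcript_id"),
        columns=samples,
    )

    expr = ExpressionMatrix(
        values=values,
        transcript_class=pd.Series(classes, index=values.index, name="class"),
        sample_group=pd.Series(groups, index=values.columns, name="group"),
    )
    truth = TruthManifest(
        de_genes=de_sets[GENE],
        de_lncrnas=de_sets[LNCRNA],
        de_mirnas=de_sets[MIRNA],
        de_sign=de_sign,
        regulator_lncrnas=regulators,
        planted_modules=modules,
    ).validate()
    return expr, truth


def _check_truth(params: SimulationParams, truth: TruthManifest) -> None:
    truth.validate()
    genes = set(gene_ids(params.n_genes))
    lncs = set(lncrna_ids(params.n_lncrnas))
    mirs = set(mirna_ids(params.n_mirnas))
    if not (truth.de_genes <= genes and truth.de_lncrnas <= lncs
            and truth.de_mirnas <= mirs):
        raise ConsistencyError("truth references transcripts outside the cohort")
    if any(not mod <= genes for mod in truth.planted_modules):
        raise ConsistencyError("planted modules reference unknown genes")


def generate_interactions(
    params: SimulationParams, truth: TruthManifest
) -> InteractionCatalog:
    """Simulate the regulatory-interaction catalog.

    Each planted regulator lncRNA targets ``regulator_mirna_out`` DE miRNAs
    and ``regulator_gene_out`` planted-module genes; each DE miRNA targets
    ``mirna_gene_out`` genes biased (3:1) toward planted-module genes; every
    other DE lncRNA receives Poisson(``background_edge_rate``) random edges.
    No self-edges, no duplicates.
    """
    params.validate()
    _check_truth(params, truth)
    rng = _rng(params, 1)

    module_genes = sorted(set().union(*truth.planted_modules)) if truth.planted_modules else []
    de_mirs = sorted(truth.de_mirnas)
    de_genes = sorted(truth.de_genes)
    all_genes = gene_ids(params.n_genes)
    all_mirs = mirna_ids(params.n_mirnas)

    edges: set[Edge] = set()

    if truth.regulator_lncrnas:
        if not de_mirs:
            raise ConsistencyError("regulators planted but no DE miRNAs exist")
        if not module_genes:
            raise ConsistencyError("regulators planted but no planted-module genes")
    for lnc in sorted(truth.regulator_lncrnas):
        k_mir = max(1, min(params.regulator_mirna_out, len(de_mirs)))
        for i in rng.choice(len(de_mirs), size=k_mir, replace=False):
            edges.add(Edge(lnc, LNCRNA, de_mirs[i], MIRNA, LNC_MIRNA))
        k_gene = max(1, min(params.regulator_gene_out, len(module_genes)))
        for i in rng.choice(len(module_genes), size=k_gene, replace=False):
            edges.add(Edge(lnc, LNCRNA, module_genes[i], GENE, LNC_GENE))

    for mir in de_mirs:
        k = min(params.mirna_gene_out, len(de_genes))
        for _ in range(k):
            pool = module_genes if (module_genes and rng.random() < 0.75) else de_genes
            tgt = pool[rng.integers(len(pool))]
            edges.add(Edge(mir, MIRNA, tgt, GENE, MIRNA_GENE))

    if params.background_edge_rate > 0 and (all_genes or all_mirs):
        for lnc in sorted(truth.de_lncrnas - truth.regulator_lncrnas):
            for _ in range(rng.poisson(params.background_edge_rate)):
                if all_mirs and (not all_genes or rng.random() < 0.3):
                    tgt = all_mirs[rng.integers(len(all_mirs))]
                    edges.add(Edge(lnc, LNCRNA, tgt, MIRNA, LNC_MIRNA))
                else:
                    tgt = all_genes[rng.integers(len(all_genes))]
                    edges.add(Edge(lnc, LNCRNA, tgt, GENE, LNC_GENE))

    return InteractionCatalog(edges)


def _decode_pairs(codes: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Map linear upper-triangle indices to (i, j) vertex pairs, i < j."""
    b = 2 * n - 1
    i = np.floor((b - np.sqrt(b * b - 8.0 * codes)) / 2.0).astype(np.int64)
    # guard against floating-point rounding at stratum boundaries
    start = i * (2 * n - i - 1) // 2
    i = np.where(codes < start, i - 1, i)
    start = i * (2 * n - i - 1) // 2
    nxt = (i + 1) * (2 * n - i - 2) // 2
    i = np.where(codes >= nxt, i + 1, i)
    start = i * (2 * n - i - 1) // 2
    j = i + 1 + (codes - start)
    return i, j


def _encode_pair(i: int, j: int, n: int) -> int:
    return i * (2 * n - i - 1) // 2 + (j - i - 1)


def generate_ppi(
    params: SimulationParams, truth: TruthManifest
) -> list[tuple[str, str]]:
    """Simulate a planted-partition PPI graph over the gene universe.

    Within each planted module every vertex pair is an edge with probability
    ``p_in``; every other pair (between modules or background) with
    probability ``p_out``.  Undirected, simple; endpoints returned sorted.
    """
    params.validate()
    _check_truth(params, truth)
    rng = _rng(params, 2)

    genes = gene_ids(params.n_genes)
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}

    within_codes: set[int] = set()
    within_pairs: list[tuple[int, int]] = []
    for mod in truth.planted_modules:
        mem = sorted(index[g] for g in mod)
        for a in range(len(mem)):
            for b in range(a + 1, len(mem)):
                i, j = mem[a], mem[b]
                within_codes.add(_encode_pair(i, j, n))
                within_pairs.append((i, j))

    edges: set[tuple[int, int]] = set()
    n_pairs = n * (n - 1) // 2
    n_bg = n_pairs - len(within_codes)
    if n_bg > 0 and params.p_out > 0:
        m = rng.binomial(n_bg, params.p_out)
        # rejection-sample distinct background pair codes
        chosen: set[int] = set()
        while len(chosen) < m:
            draw = rng.integers(0, n_pairs, size=2 * (m - len(chosen)) + 8)
            for c in draw:
                c = int(c)
                if c not in within_codes and c not in chosen:
                    chosen.add(c)
                    if len(chosen) == m:
                        break
        if chosen:
            codes = np.fromiter(sorted(chosen), dtype=np.int64)
            ii, jj = _decode_pairs(codes, n)
            edges.update(zip(ii.tolist(), jj.tolist()))

    if within_pairs:
        keep = rng.random(len(within_pairs)) < params.p_in
        edges.update(p for p, k in zip(within_pairs, keep) if k)

    return sorted((genes[i], genes[j]) for i, j in edges)


def ppi_edges_to_catalog(edges: list[tuple[str, str]]) -> InteractionCatalog:
    """Wrap a gene–gene edge list as a PPI-only interaction catalog."""
    from psanet.containers import PPI

    return InteractionCatalog(
        Edge(a, GENE, b, GENE, PPI) for a, b in edges
    )


def generate_annotations(
    params: SimulationParams, truth: TruthManifest
) -> dict[str, frozenset[str]]:
    """Simulate GMT-style annotation sets with one enriched term per module.

    The first ``n_planted_modules`` terms are designated: term ``m`` draws a
    fraction ``1 - term_random_frac`` of its members from planted module
    ``m`` (always at least 60%) and the rest from other genes.  Remaining
    terms are uniform random gene sets.  ``truth.enriched_term_per_module``
    is filled in as a side effect.
    """
    params.validate()
    _check_truth(params, truth)
    if params.term_random_frac > 0.4:
        raise ParameterError("term_random_frac above 0.4 breaks the >=60% rule")
    rng = _rng(params, 3)

    genes = gene_ids(params.n_genes)
    terms: dict[str, frozenset[str]] = {}
    mapping: dict[str, int] = {}
    n_designated = min(params.n_planted_modules, params.n_terms)
    for t in range(params.n_terms):
        term_id = f"T{t + 1:04d}"
        size = int(rng.integers(params.term_size_min, params.term_size_max + 1))
        if t < n_designated:
            module = sorted(truth.planted_modules[t])
            if params.term_random_frac < 1.0:
                size = min(size, int(len(module) / (1.0 - params.term_random_frac)))
            size = max(size, 1)
            n_mod = min(len(module), math.ceil((1.0 - params.term_random_frac) * size))
            members = {module[i] for i in rng.choice(len(module), n_mod, replace=False)}
            outside = sorted(set(genes) - set(module))
            n_out = min(size - n_mod, len(outside))
            if n_out > 0:
                members |= {
                    outside[i] for i in rng.choice(len(outside), n_out, replace=False)
                }
            mapping[term_id] = t
        else:
            size = min(size, len(genes))
            members = {genes[i] for i in rng.choice(len(genes), size, replace=False)}
        terms[term_id] = frozenset(members)

    truth.enriched_term_per_module = mapping
    return terms
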