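"""End-to-end pipeline driver.

Stages run in a fixed order — differential expression, target selection,
network construction (build, edge enrichment, augmentation, connectivity
ranking), complex detection, module enrichment and targeting — on either a
simulated study (when ``sim`` parameters are given) or files supplied via
paths.  The run is fully deterministic under a fixed seed, and a degenerate
study (no modulation, hence empty selection and empty networks) completes
without error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from psanet.containers import (
    GENE,
    LNCRNA,
    MIRNA,
    ExpressionMatrix,
    InteractionCatalog,
)
from psanet.diffexpr import FilterConfig, differential_table, filter_modulated
from psanet.enrich import (
    hypergeometric_enrichment,
    module_targeting_matrix,
    targeted_module_summary,
)
from psanet.errors import ConsistencyError, StageError
from psanet.mcode import McodeParams, find_complexes
from psanet.network import (
    augment_with_regulatory_edges,
    build_ppi_subnetwork,
    lncrna_connectivity,
    ppi_enrichment_pvalue,
    rank_lncrnas,
)
from psanet.simulate import (
    SimulationParams,
    generate_annotations,
    generate_cohort,
    generate_interactions,
    generate_ppi,
    ppi_edges_to_catalog,
)
from psanet.targets import select_targets

log = logging.getLogger("psanet")


@dataclass
class PipelineConfig:
    """Inputs, thresholds and output location for one pipeline run.

    Exactly one input mode is used: simulated (``sim`` set) or file-based
    (expression/sample-sheet/catalog paths set).  ``seed`` drives every
    source of randomness, including the simulation (overriding ``sim.seed``)
    and the permutation null of the PPI edge-enrichment test.
    """

    sim: SimulationParams | None = None
    expression_path: str | None = None
    sample_sheet_path: str | None = None
    catalog_path: str | None = None
    ppi_path: str | None = None
    gmt_path: str | None = None
    mirna_list_path: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    mcode: McodeParams = field(default_factory=McodeParams)
    enrichment_threshold: float = 0.05
    enrichment_background: str = "annotated"  # or "measured"
    top_k: int = 7
    n_perm: int = 999
    enrichment_method: str = "permutation"
    seed: int = 0
    outdir: str | None = None

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class ReportBundle:
    """Per-stage summary counts plus provenance."""

    modulated: dict[str, int]
    selection: dict[str, int]
    network: dict
    top_lncrnas: list[str]
    modules: dict
    targeting: dict
    enrichment: dict
    provenance: dict

    def validate(self) -> "ReportBundle":
        if self.targeting["n_targeted_modules"] > self.modules["n_modules"]:
            raise ConsistencyError("targeted modules exceed total modules")
        if self.network["n_connected_nodes"] > self.network["n_nodes"]:
            raise ConsistencyError("connected nodes exceed node count")
        if len(self.top_lncrnas) > max(0, self.selection["selected_lncrnas"]):
            raise ConsistencyError("more ranked lncRNAs than selected ones")
        return self

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _load_inputs(config: PipelineConfig):
    from psanet import io

    if config.sim is not None:
        params = dataclasses.replace(config.sim, seed=config.seed)
        expr, truth = generate_cohort(params)
        catalog = generate_interactions(params, truth).merge(
            ppi_edges_to_catalog(generate_ppi(params, truth))
        )
        terms = generate_annotations(params, truth)
        return expr, catalog, terms, None, truth
    if not (config.expression_path and config.sample_sheet_path
            and config.catalog_path):
        raise ConsistencyError(
            "either sim params or expression/sample-sheet/catalog paths required"
        )
    expr = io.read_expression(config.expression_path, config.sample_sheet_path)
    catalog = io.read_catalog(config.catalog_path)
    if config.ppi_path:
        catalog = catalog.merge(
            ppi_edges_to_catalog(io.read_ppi_edges(config.ppi_path))
        )
    terms = io.read_gmt(config.gmt_path) if config.gmt_path else {}
    mirna_list = (
        io.read_id_list(config.mirna_list_path)
        if config.mirna_list_path
        else None
    )
    return expr, catalog, terms, mirna_list, None


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage in order; write artifacts if ``outdir`` is set."""
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / ".incomplete").write_text("run in progress\n")
    try:
        report = _run(config, outdir)
    except StageError:
        raise
    except Exception as exc:  # pragma: no cover - defensive stage labeling
        raise StageError("pipeline", str(exc)) from exc
    if outdir:
        (outdir / ".incomplete").unlink(missing_ok=True)
    return report


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


def _run(config: PipelineConfig, outdir: Path | None) -> ReportBundle:
    from psanet import io

    meta = {"seed": config.seed, "package": "psanet"}

    expr, catalog, terms, external_mirnas, truth = _stage("inputs")(_load_inputs)(
        config
    )
    log.info("inputs: %d transcripts, %d samples, %d catalog edges",
             expr.values.shape[0], expr.values.shape[1], len(catalog))
    if outdir and truth is not None:
        io.write_manifest(truth, outdir / "manifest.json")
        io.write_expression(expr, outdir / "expression.tsv",
                            outdir / "samples.tsv", meta)
        io.write_catalog(catalog, outdir / "catalog.tsv", meta)
        if terms:
            io.write_gmt(terms, outdir / "annotations.gmt")

    # -- differential expression -------------------------------------------
    table = _stage("diffexpr")(differential_table)(expr, config.filter)
    parts = filter_modulated(table, config.filter)
    mod_genes = frozenset(parts.get(GENE, table.iloc[0:0]).index)
    mod_lncrnas = frozenset(parts.get(LNCRNA, table.iloc[0:0]).index)
    mod_mirnas_called = frozenset(parts.get(MIRNA, table.iloc[0:0]).index)
    mirna_list = external_mirnas if external_mirnas is not None else mod_mirnas_called
    log.info("diffexpr: %d genes, %d lncRNAs, %d miRNAs modulated",
             len(mod_genes), len(mod_lncrnas), len(mirna_list))
    if outdir:
        io.write_differential(table, outdir / "differential.tsv", meta)

    # -- target selection ---------------------------------------------------
    selection = _stage("target_selection")(select_targets)(
        mod_lncrnas, mod_genes, mirna_list, catalog
    )
    log.info("selection: %s", selection.summary)
    if outdir:
        io.write_selection(selection, outdir, meta)

    # -- network ------------------------------------------------------------
    @_stage("network")
    def _network():
        net, stats_ = build_ppi_subnetwork(selection.target_gene_universe,
                                           catalog)
        if stats_.n_nodes >= 2 and catalog.gene_universe():
            stats_.enrichment_p = ppi_enrichment_pvalue(
                net, catalog, method=config.enrichment_method,
                n_perm=config.n_perm, seed=config.seed + 1,
            )
        net = augment_with_regulatory_edges(net, selection)
        profiles = lncrna_connectivity(net)
        top = rank_lncrnas(profiles, config.top_k)
        return net, stats_, profiles, top

    net, net_stats, profiles, top = _network()
    log.info("network: %d nodes, %d edges, %d connected, enrichment p=%s",
             net_stats.n_nodes, net_stats.n_edges,
             net_stats.n_connected_nodes, net_stats.enrichment_p)
    if outdir:
        io.write_graphml(net, outdir / "network.graphml")
        io.write_network_edges(net, outdir / "network_edges.tsv", meta)

    # -- complex detection on the full modulated-gene PPI network -----------
    @_stage("mcode")
    def _modules():
        wide_net, _ = build_ppi_subnetwork(mod_genes, catalog)
        return find_complexes(wide_net.ppi, config.mcode)

    modules = _modules()
    log.info("mcode: %d modules, sizes %s", len(modules),
             [len(m.members) for m in modules])
    if outdir:
        io.write_modules(modules, outdir / "modules.tsv",
                         outdir / "modules.json", meta)

    # -- module enrichment ---------------------------------------------------
    @_stage("enrichment")
    def _enrichment():
        measured = frozenset(expr.ids_of_class(GENE))
        if config.enrichment_background == "measured" or not terms:
            background = measured
        else:
            annotated = frozenset().union(*terms.values()) if terms else frozenset()
            background = measured & annotated
        records = []
        for m in modules:
            inside = m.members & background
            if not terms or not inside:
                continue
            records.extend(
                hypergeometric_enrichment(
                    inside, terms, background,
                    threshold=config.enrichment_threshold,
                    module_label=m.label,
                )
            )
        return records

    enrichment_records = _enrichment()
    if outdir:
        io.write_enrichment(enrichment_records, outdir / "enrichment.tsv", meta)

    # -- targeting matrix ----------------------------------------------------
    @_stage("targeting")
    def _targeting():
        wide_vertices = frozenset().union(*(m.members for m in modules)) \
            if modules else frozenset()
        matrix = module_targeting_matrix(
            modules, selection,
            dataclasses.replace(net, gene_vertices=net.gene_vertices | wide_vertices),
        )
        counts, fraction = targeted_module_summary(matrix)
        return matrix, counts, fraction

    matrix, counts, fraction = _targeting()
    log.info("targeting: %d/%d modules targeted",
             len(matrix.targeted_modules()), len(modules))
    if outdir:
        io.write_targeting_matrix(matrix, outdir / "targeting.tsv", meta)

    n_sig = sum(1 for r in enrichment_records if r.significant)
    top_terms = {}
    for r in enrichment_records:
        if r.module_label not in top_terms:
            top_terms[r.module_label] = {"term": r.term_id, "p": r.p_hg}

    report = ReportBundle(
        modulated={
            GENE: len(mod_genes),
            LNCRNA: len(mod_lncrnas),
            MIRNA: len(mod_mirnas_called),
            "mirna_list_used": len(mirna_list),
        },
        selection=dict(selection.summary),
        network={
            "n_nodes": net_stats.n_nodes,
            "n_edges": net_stats.n_edges,
            "n_connected_nodes": net_stats.n_connected_nodes,
            "enrichment_p": net_stats.enrichment_p,
        },
        top_lncrnas=list(top),
        modules={
            "n_modules": len(modules),
            "labels": [m.label for m in modules],
            "sizes": [len(m.members) for m in modules],
            "scores": [m.score for m in modules],
        },
        targeting={
            "per_lncrna_counts": counts,
            "n_targeted_modules": len(matrix.targeted_modules()),
            "targeted_fraction": fraction,
        },
        enrichment={
            "n_records": len(enrichment_records),
            "n_significant": n_sig,
            "top_term_per_module": top_terms,
        },
        provenance={
            "seed": config.seed,
            "config": config.echo(),
            "package_version": __import__("psanet").__version__,
        },
    ).validate()

    if outdir:
        (outdir / "report.json").write_text(report.to_json() + "\n")
    return report
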