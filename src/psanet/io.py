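"""Readers and writers for the pipeline's tabular and graph formats.

All tabular outputs are headered TSV; writers accept a ``meta`` mapping that
is emitted as ``#key=value`` comment lines above the header so every file is
self-describing (readers skip ``#`` lines).  Annotation sets use the GMT
format; networks are exported as GraphML with a ``vclass`` vertex attribute
(gene / lncRNA / miRNA) and an ``etype`` edge attribute.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from psanet.containers import (
    GENE,
    LNCRNA,
    MIRNA,
    Edge,
    ExpressionMatrix,
    InteractionCatalog,
)
from psanet.enrich import EnrichmentRecord, NONE, TargetingMatrix
from psanet.mcode import ModuleRecord
from psanet.network import TriLayerNetwork
from psanet.simulate import TruthManifest
from psanet.targets import SelectionResult


def _write_meta(handle, meta: Mapping | None) -> None:
    for key in sorted(meta or {}):
        handle.write(f"#{key}={meta[key]}\n")


def _to_tsv(df: pd.DataFrame, path, meta=None, index=True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        _write_meta(fh, meta)
        df.to_csv(fh, sep="\t", index=index)


# -- expression -------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, matrix_path, samples_path, meta=None):
    mat = expr.values.copy()
    mat.insert(0, "transcript_class", expr.transcript_class)
    _to_tsv(mat, matrix_path, meta)
    sheet = expr.sample_group.rename("group").to_frame()
    sheet.index.name = "sample_id"
    _to_tsv(sheet, samples_path, meta)


def read_expression(matrix_path, samples_path) -> ExpressionMatrix:
    mat = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    sheet = pd.read_csv(samples_path, sep="\t", comment="#", index_col=0)
    classes = mat.pop("transcript_class")
    return ExpressionMatrix(
        values=mat.astype(float),
        transcript_class=classes,
        sample_group=sheet["group"],
    )


# -- interaction catalogs ---------------------------------------------------

_CATALOG_COLS = ["source_id", "source_class", "target_id", "target_class",
                 "interaction_type"]


def write_catalog(catalog: InteractionCatalog, path, meta=None) -> None:
    rows = [
        (e.source, e.source_class, e.target, e.target_class, e.etype)
        for e in catalog
    ]
    _to_tsv(pd.DataFrame(rows, columns=_CATALOG_COLS), path, meta, index=False)


def read_catalog(path) -> InteractionCatalog:
    df = pd.read_csv(path, sep="\t", comment="#")
    return InteractionCatalog(
        Edge(r.source_id, r.source_class, r.target_id, r.target_class,
             r.interaction_type)
        for r in df.itertuples()
    )


def write_ppi_edges(edges: Iterable[tuple[str, str]], path, meta=None) -> None:
    df = pd.DataFrame(sorted(edges), columns=["gene_a", "gene_b"])
    _to_tsv(df, path, meta, index=False)


def read_ppi_edges(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [(str(a), str(b)) for a, b in zip(df["gene_a"], df["gene_b"])]


# -- GMT annotation sets ----------------------------------------------------

def write_gmt(terms: Mapping[str, Iterable[str]], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for term_id in sorted(terms):
            genes = "\t".join(sorted(terms[term_id]))
            fh.write(f"{term_id}\t{term_id}\t{genes}\n")


def read_gmt(path) -> dict[str, frozenset[str]]:
    terms: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            terms[parts[0]] = frozenset(g for g in parts[2:] if g)
    return terms


# -- truth manifests --------------------------------------------------------

def write_manifest(truth: TruthManifest, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(truth.to_json() + "\n")


def read_manifest(path) -> TruthManifest:
    return TruthManifest.from_json(Path(path).read_text())


# -- differential tables ----------------------------------------------------

def write_differential(table: pd.DataFrame, path, meta=None) -> None:
    out = table.copy()
    out.index.name = "transcript_id"
    _to_tsv(out, path, meta)


def read_differential(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_id_list(ids: Iterable[str], path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("".join(f"{i}\n" for i in sorted(set(ids))))


def read_id_list(path) -> frozenset[str]:
    lines = Path(path).read_text().splitlines()
    return frozenset(s.strip() for s in lines if s.strip() and not s.startswith("#"))


# -- selections -------------------------------------------------------------

def write_selection(selection: SelectionResult, outdir, meta=None) -> None:
    outdir = Path(outdir)
    for name, edges in [
        ("lnc_gene_edges.tsv", selection.lnc_gene_edges),
        ("lnc_mirna_edges.tsv", selection.lnc_mirna_edges),
        ("mirna_gene_edges.tsv", selection.mirna_gene_edges),
    ]:
        write_catalog(InteractionCatalog(edges), outdir / name, meta)
    payload = {
        "selected_lncrnas": sorted(selection.selected_lncrnas),
        "summary": selection.summary,
    }
    (outdir / "selection.json").write_text(json.dumps(payload, indent=2,
                                                      sort_keys=True) + "\n")


def read_selection(outdir) -> SelectionResult:
    outdir = Path(outdir)
    payload = json.loads((outdir / "selection.json").read_text())
    return SelectionResult(
        selected_lncrnas=frozenset(payload["selected_lncrnas"]),
        lnc_gene_edges=read_catalog(outdir / "lnc_gene_edges.tsv").edges,
        lnc_mirna_edges=read_catalog(outdir / "lnc_mirna_edges.tsv").edges,
        mirna_gene_edges=read_catalog(outdir / "mirna_gene_edges.tsv").edges,
        summary=payload["summary"],
    ).recount()


# -- networks ---------------------------------------------------------------

def network_to_graph(network: TriLayerNetwork) -> nx.DiGraph:
    """Flatten the tri-layer network into one typed directed graph.

    PPI edges are undirected in nature and appear once, with
    ``etype="ppi"``; regulatory edges keep their direction.
    """
    g = nx.DiGraph()
    for v in sorted(network.gene_vertices):
        g.add_node(v, vclass=GENE)
    for a, b in sorted(network.ppi.edges):
        g.add_edge(*sorted((a, b)), etype="ppi")
    for edges in (network.lnc_gene_edges, network.lnc_mirna_edges,
                  network.mirna_gene_edges):
        for e in sorted(edges):
            g.add_node(e.source, vclass=e.source_class)
            if e.target not in g:
                g.add_node(e.target, vclass=e.target_class)
            g.add_edge(e.source, e.target, etype=e.etype)
    return g


def write_graphml(network: TriLayerNetwork, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(network_to_graph(network), path)


def write_network_edges(network: TriLayerNetwork, path, meta=None) -> None:
    g = network_to_graph(network)
    rows = [
        (a, g.nodes[a]["vclass"], b, g.nodes[b]["vclass"], d["etype"])
        for a, b, d in g.edges(data=True)
    ]
    rows.sort()
    _to_tsv(pd.DataFrame(rows, columns=_CATALOG_COLS), path, meta, index=False)


# -- modules, enrichment, targeting ----------------------------------------

def write_modules(modules: Iterable[ModuleRecord], tsv_path, json_path=None,
                  meta=None) -> None:
    modules = list(modules)
    rows = [
        (m.label, member, len(m.members), round(m.density, 6), round(m.score, 6))
        for m in modules
        for member in sorted(m.members)
    ]
    df = pd.DataFrame(rows, columns=["label", "member", "size", "density",
                                     "score"])
    _to_tsv(df, tsv_path, meta, index=False)
    if json_path is not None:
        payload = [
            {
                "label": m.label,
                "members": sorted(m.members),
                "density": m.density,
                "score": m.score,
            }
            for m in modules
        ]
        Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")


def read_modules(json_path) -> list[ModuleRecord]:
    payload = json.loads(Path(json_path).read_text())
    return [
        ModuleRecord(
            label=m["label"],
            members=frozenset(m["members"]),
            density=float(m["density"]),
            score=float(m["score"]),
            contains_kcore_k=True,
        )
        for m in payload
    ]


def write_enrichment(records: Iterable[EnrichmentRecord], path, meta=None):
    rows = [
        (r.module_label, r.term_id, r.N, r.K, r.n, r.k, r.p_hg, r.p_bh,
         r.significant)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["module", "term", "N", "K", "n", "k",
                                     "p", "p_bh", "significant"])
    _to_tsv(df, path, meta, index=False)


def write_targeting_matrix(matrix: TargetingMatrix, path, meta=None) -> None:
    df = pd.DataFrame(
        {
            label: [matrix.cell(lnc, label) for lnc in matrix.lncrnas]
            for label in matrix.module_labels
        },
        index=pd.Index(matrix.lncrnas, name="lncrna"),
    )
    if df.empty and not matrix.lncrnas:
        df = pd.DataFrame(columns=matrix.module_labels,
                          index=pd.Index([], name="lncrna"))
    _to_tsv(df, path, meta)


def read_targeting_matrix(path) -> TargetingMatrix:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    matrix = TargetingMatrix(
        lncrnas=[str(i) for i in df.index],
        module_labels=[str(c) for c in df.columns],
    )
    for lnc in df.index:
        for label in df.columns:
            value = df.loc[lnc, label]
            if value != NONE:
                matrix.cells[(str(lnc), str(label))] = str(value)
    return matrix
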