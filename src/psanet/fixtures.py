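"""Bundled worked-example fixtures.

Two small published tables ship with the package as plain TSV: a list of 40
modulated lncRNAs (signed fold change and p-value, as printed) and the
lncRNA→gene / lncRNA→miRNA target table over the same 40 lncRNAs.  A
p-value printed as ``<0.0001`` is parsed as 0.0001 with an upper-bound flag.
The 15-identifier modulated-miRNA list is the external input the selection
cascade expects (it comes from a prior miRNA profiling study of the same
cohort, not from a computation in this package).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from psanet.containers import (
    GENE,
    LNCRNA,
    LNC_GENE,
    LNC_MIRNA,
    MIRNA,
    Edge,
    InteractionCatalog,
)
from psanet.diffexpr import DifferentialRecord, FilterConfig

#: modulated miRNAs reported by the prior profiling of the same cohort
MODULATED_MIRNAS: tuple[str, ...] = (
    "hsa-miR-130a-3p",
    "hsa-miR-148a-3p",
    "hsa-miR-151a-5p",
    "hsa-miR-17-5p",
    "hsa-miR-186-5p",
    "hsa-miR-199a-3p",
    "hsa-miR-199a-5p",
    "hsa-miR-28-5p",
    "hsa-miR-3135b",
    "hsa-miR-320c",
    "hsa-miR-320d",
    "hsa-miR-331-3p",
    "hsa-miR-423-5p",
    "hsa-miR-451a",
    "hsa-miR-92a-3p",
)


def _data_path(name: str):
    return resources.files("psanet").joinpath("data", name)


def table1_dataframe() -> pd.DataFrame:
    """The raw 40-row lncRNA table (probe id, fold change, p, symbol, accession)."""
    with resources.as_file(_data_path("table1_lncrnas.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype=str)


def load_table1_fixture(
    config: FilterConfig | None = None,
) -> list[DifferentialRecord]:
    """The 40 modulated lncRNAs as differential records.

    Record ids are the gene symbols (the identifiers used by the target
    table).  The printed table reports one p-value per row; the decision
    p-value therefore defaults to raw mode.  ``p_adj`` is set equal to the
    printed p (the original correction multiplicity is not recoverable from
    the table).
    """
    config = config or FilterConfig(p_mode="raw")
    records = []
    for row in table1_dataframe().itertuples():
        raw = str(row.p_value).strip()
        upper = raw.startswith("<")
        p = float(raw.lstrip("<"))
        fc = float(row.fold_change)
        records.append(
            DifferentialRecord(
                transcript_id=str(row.gene_symbol).strip(),
                transcript_class=LNCRNA,
                fc=fc,
                p_raw=p,
                p_adj=p,
                modulated=(
                    abs(fc) >= config.fc_threshold and p <= config.p_threshold
                ),
                p_upper_bound=upper,
            )
        )
    return records


def load_table2_fixture() -> InteractionCatalog:
    """The lncRNA target table as an interaction catalog.

    Gene targets become ``lnc_gene`` edges, miRNA targets ``lnc_mirna``
    edges; one edge per printed (lncRNA, target) pair.
    """
    with resources.as_file(_data_path("table2_lncrna_targets.tsv")) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    edges = []
    for row in df.itertuples():
        if row.target_class == "gene":
            edges.append(Edge(row.lncrna, LNCRNA, row.target, GENE, LNC_GENE))
        else:
            edges.append(Edge(row.lncrna, LNCRNA, row.target, MIRNA, LNC_MIRNA))
    return InteractionCatalog(edges)
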