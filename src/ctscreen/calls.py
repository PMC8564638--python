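"""Intersection of tissue and cancer classifications into CT calls.

A probeset is a *CT candidate* when it is testis-expressed (class SET,
SEHET, PET or PEHET) and upregulated in at least one cancer subtype whose
matched normal tissue shows no detectable expression (any-subtype UCNDH).
The *core CT* set restricts the tissue side to the strictly testis-specific
classes SET and SEHET. Probeset calls are collapsed to gene level by the
any-probeset rule; probesets without a gene symbol are counted at probeset
level only and flagged unmapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConsistencyError
from .model import ProbesetAnnotation
from .tissue import SE_CLASSES, TESTIS_CLASSES, summarize_class_distribution


@dataclass
class CTCallTable:
    """Probeset- and gene-level CT calls.

    ``probesets`` columns: gene_symbol, tissue_class, any_ucndh,
    ct_candidate, core_ct, unmapped. ``genes`` columns: n_probesets,
    n_ct_probesets, ct_candidate, core_ct (one row per mapped gene).
    """

    probesets: pd.DataFrame
    genes: pd.DataFrame

    def write(self, probeset_path, gene_path) -> None:
        out = self.probesets.copy()
        for c in ("any_ucndh", "ct_candidate", "core_ct", "unmapped"):
            out[c] = out[c].astype(int)
        out.rename_axis("probeset_id").to_csv(probeset_path, sep="\t")
        gout = self.genes.copy()
        for c in ("ct_candidate", "core_ct"):
            gout[c] = gout[c].astype(int)
        gout.rename_axis("gene_symbol").to_csv(gene_path, sep="\t")


def call_ct(
    tissue_records: pd.DataFrame,
    cancer_aggregate: pd.DataFrame,
    probe_annot: ProbesetAnnotation,
) -> CTCallTable:
    """Intersect tissue classes with the any-subtype UCNDH flag."""
    t_idx = tissue_records.index
    c_idx = cancer_aggregate.index
    if set(t_idx) != set(c_idx):
        raise ConsistencyError(
            "tissue and cancer tables cover different probeset sets "
            f"({len(t_idx.difference(c_idx))} only-tissue, "
            f"{len(c_idx.difference(t_idx))} only-cancer)"
        )
    any_ucndh = cancer_aggregate["any_ucndh"].reindex(t_idx)
    tissue_class = tissue_records["class_label"]
    gene = probe_annot.gene_for(t_idx)
    gene.index = t_idx
    probesets = pd.DataFrame(
        {
            "gene_symbol": gene,
            "tissue_class": tissue_class,
            "any_ucndh": any_ucndh,
            "ct_candidate": tissue_class.isin(TESTIS_CLASSES) & any_ucndh,
            "core_ct": tissue_class.isin(SE_CLASSES) & any_ucndh,
            "unmapped": gene == "",
        },
        index=t_idx.rename("probeset_id"),
    )
    mapped = probesets[~probesets["unmapped"]]
    g = mapped.groupby("gene_symbol", sort=True)
    genes = pd.DataFrame(
        {
            "n_probesets": g.size(),
            "n_ct_probesets": g["ct_candidate"].sum().astype(int),
            "ct_candidate": g["ct_candidate"].any(),
            "core_ct": g["core_ct"].any(),
        }
    )
    genes.index.name = "gene_symbol"
    return CTCallTable(probesets=probesets, genes=genes)


@dataclass
class FlowchartReport:
    """Probeset/gene counts for each screening step plus the class table."""

    n_probesets: int
    n_genes: int
    step1_probesets: int          # testis-expressed (SET/SEHET/PET/PEHET)
    step1_genes: int
    step2_probesets: int          # UCNDH in >= 1 cancer subtype
    step2_genes: int
    ct_probesets: int             # intersection
    ct_genes: int
    core_probesets: int           # SET/SEHET intersection
    core_genes: int
    class_distribution: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        d = {
            k: getattr(self, k)
            for k in (
                "n_probesets", "n_genes",
                "step1_probesets", "step1_genes",
                "step2_probesets", "step2_genes",
                "ct_probesets", "ct_genes",
                "core_probesets", "core_genes",
            )
        }
        for cls, row in self.class_distribution.iterrows():
            d[f"class_{cls}"] = int(row["count"])
        return d

    def to_kv(self) -> str:
        return "\n".join(f"{k}={v}" for k, v in self.to_dict().items()) + "\n"

    def to_text(self) -> str:
        lines = [
            "CT screening flowchart",
            f"  input:          {self.n_probesets} probesets ({self.n_genes} genes)",
            f"  step 1 (testis-expressed): {self.step1_probesets} probesets "
            f"({self.step1_genes} genes)",
            f"  step 2 (UCNDH):            {self.step2_probesets} probesets "
            f"({self.step2_genes} genes)",
            f"  CT candidates (1 ∩ 2):     {self.ct_probesets} probesets "
            f"({self.ct_genes} genes)",
            f"  core CT (SET/SEHET ∩ 2):   {self.core_probesets} probesets "
            f"({self.core_genes} genes)",
            "",
            "Tissue class distribution:",
        ]
        for cls, row in self.class_distribution.iterrows():
            lines.append(f"  {cls:6s} {int(row['count']):6d}  ({int(row['percentage'])}%)")
        return "\n".join(lines) + "\n"


def _gene_count(probesets: pd.Index, gene: pd.Series) -> int:
    symbols = gene.reindex(probesets)
    return int(symbols[symbols != ""].nunique())


def flowchart_report(
    tissue_records: pd.DataFrame,
    cancer_aggregate: pd.DataFrame,
    calls: CTCallTable,
    probe_annot: ProbesetAnnotation,
) -> FlowchartReport:
    """Count every screening step at probeset and gene level."""
    idx = tissue_records.index
    gene = probe_annot.gene_for(idx)
    gene.index = idx
    step1 = idx[tissue_records["class_label"].isin(TESTIS_CLASSES)]
    step2 = idx[cancer_aggregate["any_ucndh"].reindex(idx).fillna(False)]
    ct = calls.probesets.index[calls.probesets["ct_candidate"]]
    core = calls.probesets.index[calls.probesets["core_ct"]]
    return FlowchartReport(
        n_probesets=len(idx),
        n_genes=_gene_count(idx, gene),
        step1_probesets=len(step1),
        step1_genes=_gene_count(step1, gene),
        step2_probesets=len(step2),
        step2_genes=_gene_count(step2, gene),
        ct_probesets=len(ct),
        ct_genes=_gene_count(ct, gene),
        core_probesets=len(core),
        core_genes=_gene_count(core, gene),
        class_distribution=summarize_class_distribution(tissue_records),
    )
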