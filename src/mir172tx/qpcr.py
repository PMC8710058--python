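"""Relative quantification by 2^-ddCt and RNA-seq concordance.

ddCt = (Ct_target,treatment - Ct_ref,treatment)
     - (Ct_target,control  - Ct_ref,control);
relative expression = 2^-ddCt, with the target normalized to a reference
gene of constant expression. Technical replicates are averaged on the Ct
scale before the subtraction. Concordance with RNA-seq is sign agreement
between log2(2^-ddCt) and the contrast's log2 fold change, per gene and
comparison; points with either |value| inside a declared dead zone are
excluded from the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["relative_expression", "ddct_from_table", "concordance", "ConcordanceReport"]


def relative_expression(
    ct_target_treatment: float,
    ct_ref_treatment: float,
    ct_target_control: float,
    ct_ref_control: float,
) -> float:
    """2^-ddCt for one gene in one treatment/control comparison."""
    ddct = (ct_target_treatment - ct_ref_treatment) - (
        ct_target_control - ct_ref_control
    )
    return 2.0 ** (-ddct)


def ddct_from_table(
    ct_table: pd.DataFrame,
    reference_gene: str,
    treatment_genotype: str = "miR172OX",
    control_genotype: str = "WT",
) -> pd.DataFrame:
    """Per gene x (tissue, timepoint) 2^-ddCt from a long-format Ct table.

    Expects columns gene_id, genotype, tissue, timepoint, tech_rep, ct.
    Technical replicates and then biological libraries are averaged on the
    Ct scale within each (gene, genotype, tissue, timepoint) cell.
    """
    need = {"gene_id", "genotype", "tissue", "timepoint", "ct"}
    missing = need - set(ct_table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    mean_ct = (
        ct_table.groupby(["gene_id", "genotype", "tissue", "timepoint"])["ct"]
        .mean()
        .rename("ct")
    )
    if reference_gene not in ct_table["gene_id"].unique():
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")
    rows = []
    targets = [g for g in ct_table["gene_id"].unique() if g != reference_gene]
    cells = ct_table[["tissue", "timepoint"]].drop_duplicates()
    for gene in targets:
        for _, cell in cells.iterrows():
            key_t = (gene, treatment_genotype, cell["tissue"], cell["timepoint"])
            key_c = (gene, control_genotype, cell["tissue"], cell["timepoint"])
            ref_t = (reference_gene, treatment_genotype, cell["tissue"], cell["timepoint"])
            ref_c = (reference_gene, control_genotype, cell["tissue"], cell["timepoint"])
            try:
                rel = relative_expression(
                    mean_ct.loc[key_t], mean_ct.loc[ref_t], mean_ct.loc[key_c], mean_ct.loc[ref_c]
                )
            except KeyError:
                continue
            rows.append(
                (gene, cell["tissue"], int(cell["timepoint"]), rel, math.log2(rel))
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "tissue", "timepoint", "rel_expr", "log2_ratio"]
    )


@dataclass
class ConcordanceReport:
    """Sign agreement between qPCR log2 ratios and RNA-seq log2FC."""

    points: pd.DataFrame  # gene_id, comparison, qpcr_log2, rnaseq_log2fc, concordant
    concordant_fraction: float | None  # None when no usable points
    n_used: int
    n_excluded: int

    @property
    def has_data(self) -> bool:
        return self.concordant_fraction is not None


def concordance(
    qpcr: pd.DataFrame,
    rnaseq_log2fc: dict[str, dict[str, float]],
    dead_zone: float = 0.0,
) -> ConcordanceReport:
    """Fraction of gene x comparison points whose signs agree.

    ``qpcr`` needs columns gene_id, comparison, log2_ratio; ``rnaseq_log2fc``
    maps comparison -> gene -> log2FC. Points missing on either side are
    ignored; points with |log2 ratio| or |log2FC| <= ``dead_zone`` are
    excluded from the denominator.
    """
    rows = []
    n_excluded = 0
    for r in qpcr.itertuples(index=False):
        comp = r.comparison
        gene = r.gene_id
        if comp not in rnaseq_log2fc or gene not in rnaseq_log2fc[comp]:
            continue
        q = float(r.log2_ratio)
        s = float(rnaseq_log2fc[comp][gene])
        if abs(q) <= dead_zone or abs(s) <= dead_zone:
            n_excluded += 1
            continue
        rows.append((gene, comp, q, s, (q > 0) == (s > 0)))
    points = pd.DataFrame(
        rows, columns=["gene_id", "comparison", "qpcr_log2", "rnaseq_log2fc", "concordant"]
    )
    frac = float(points["concordant"].mean()) if len(points) else None
    return ConcordanceReport(
        points=points,
        concordant_fraction=frac,
        n_used=len(points),
        n_excluded=n_excluded,
    )
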