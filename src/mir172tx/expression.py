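"""FPKM normalization, low-expression filtering, and replicate QC.

FPKM[g, j] = counts[g, j] * 1e9 / (length_bp[g] * total_counts[j]),
with the denominator taken from the count matrix itself so results are
reproducible from the inputs alone. Correlations are computed on
log2(FPKM + 1); the pseudocount is the conventional 1 and is exposed
where it matters.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, ExpressionMatrix, GeneAnnotation, SampleSheet

__all__ = ["compute_fpkm", "filter_low_expression", "replicate_qc", "ReplicateQCReport"]


def compute_fpkm(counts: CountMatrix, annot: GeneAnnotation) -> ExpressionMatrix:
    """Fragments per kilobase of transcript per million mapped reads."""
    totals = counts.counts.sum(axis=0).astype(float)
    for j, lib in enumerate(counts.library_ids):
        if totals[j] <= 0:
            raise ValueError(f"library {lib!r} has zero total counts")
    lengths = annot.lengths_for(counts.gene_ids)  # raises naming missing gene
    fpkm = counts.counts * 1e9 / (lengths[:, None] * totals[None, :])
    return ExpressionMatrix(
        pd.DataFrame(fpkm, index=counts.gene_ids, columns=counts.library_ids)
    )


def filter_low_expression(expr: ExpressionMatrix, threshold: float = 2.0) -> list[str]:
    """Genes whose FPKM exceeds ``threshold`` in at least one library (strict >)."""
    keep = (expr.values > threshold).any(axis=1)
    return [g for g, k in zip(expr.gene_ids, keep) if k]


@dataclass
class ReplicateQCReport:
    """Pairwise replicate R-squared per (genotype, tissue, timepoint) group.

    ``pairs`` has one row per replicate pair (group, lib_a, lib_b, r2);
    ``summary`` one row per group (n_pairs, min/median/max R2, flagged).
    """

    pairs: pd.DataFrame
    summary: pd.DataFrame
    skipped_groups: list[tuple]

    @property
    def r2_range(self) -> tuple[float, float]:
        return float(self.pairs["r2"].min()), float(self.pairs["r2"].max())


def replicate_qc(
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    pseudocount: float = 1.0,
    flag_threshold: float = 0.8,
) -> ReplicateQCReport:
    """Pairwise Pearson R^2 between replicate libraries on log2(FPKM + pc).

    Groups with fewer than two replicates are skipped (and listed). A
    group is flagged when its minimum pairwise R^2 falls below
    ``flag_threshold``.
    """
    log_expr = np.log2(expr.values + pseudocount)
    col = {lib: j for j, lib in enumerate(expr.library_ids)}
    pair_rows, summary_rows, skipped = [], [], []
    for key in sheet.group_sizes():
        libs = [l for l in sheet.libraries_for(*key) if l in col]
        if len(libs) < 2:
            skipped.append(key)
            continue
        r2s = []
        for a, b in itertools.combinations(libs, 2):
            r = np.corrcoef(log_expr[:, col[a]], log_expr[:, col[b]])[0, 1]
            r2 = float(r * r)
            r2s.append(r2)
            pair_rows.append(("/".join(map(str, key)), a, b, r2))
        summary_rows.append(
            (
                "/".join(map(str, key)),
                len(r2s),
                min(r2s),
                float(np.median(r2s)),
                max(r2s),
                min(r2s) < flag_threshold,
            )
        )
    return ReplicateQCReport(
        pairs=pd.DataFrame(pair_rows, columns=["group", "lib_a", "lib_b", "r2"]),
        summary=pd.DataFrame(
            summary_rows,
            columns=["group", "n_pairs", "min_r2", "median_r2", "max_r2", "flagged"],
        ),
        skipped_groups=skipped,
    )
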