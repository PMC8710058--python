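#!/usr/bin/env python
"""Call DEGs per contrast with the simplified NB Wald test.

Five contrasts: miR172OX vs WT in whole fruit (2 WPFB) and in skin,
flesh and core (4 WPFB), plus 'M9' vs 'Hanfu' whole fruit (4 WPFB).
Thresholds: BH-adjusted p < 0.05 and |log2FC| > 1; at 4 WPFB a gene
qualifying in any tissue is a DEG. Writes per-contrast tables and the
combined DEG table under results/.
"""

from pathlib import Path

import pandas as pd

from mir172tx import diffexpr, expression
from mir172tx.io_formats import (
    read_count_matrix,
    read_gene_annotation,
    read_sample_sheet,
    write_deg_table,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    counts = read_count_matrix(ROOT / "data" / "counts.tsv")
    sheet = read_sample_sheet(ROOT / "data" / "samples.tsv")
    annot = read_gene_annotation(ROOT / "data" / "annotation.tsv")
    fpkm = expression.compute_fpkm(counts, annot)
    retained = set(expression.filter_low_expression(fpkm))

    contrasts = diffexpr.contrasts_for_design(sheet, counts)
    sub = counts.subset_genes(retained)
    rows = []
    for name, contrast in contrasts.items():
        res = diffexpr.nb_wald_test(sub, contrast)
        res.table.to_csv(ROOT / f"de_{name}.tsv", sep="\t", float_format="%.6g")
        degs = diffexpr.call_degs(res, retained)
        for g in sorted(degs.all):
            r = res.table.loc[g]
            rows.append((g, name, r["log2fc"], r["pvalue"], r["padj"],
                         "up" if g in degs.up else "down"))
        print(f"{name}: {len(degs.up)} up, {len(degs.down)} down")
    write_deg_table(
        pd.DataFrame(rows, columns=["gene_id", "contrast", "log2fc", "pvalue", "padj", "direction"]),
        ROOT / "degs.tsv",
    )
    print(f"wrote per-contrast tables and {len(rows)} DEG calls to {ROOT}")


if __name__ == "__main__":
    main()
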