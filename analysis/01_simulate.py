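#!/usr/bin/env python
"""Generate the synthetic two-experiment apple fruit study.

30 libraries: miR172OX vs WT whole fruit at 2 WPFB plus skin/flesh/core
at 4 WPFB (24 libraries), and 'M9' vs 'Hanfu' whole fruit at 4 WPFB (6
libraries); 5,000 genes with planted miR172-specific, shared-same and
shared-opposite DEG classes, three coexpression modules (one carrying a
MYB/bHLH/WD40 triad and a structural guide gene), and a matching qPCR
Ct table. Writes the study under results/data/.
"""

from pathlib import Path

from mir172tx import expression, synthetic
from mir172tx.io_formats import (
    write_count_matrix,
    write_gene_annotation,
    write_sample_sheet,
)

SEED = 20240401
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = synthetic.SimulationConfig(seed=SEED)
    counts, sheet, annot, truth = synthetic.simulate_counts(cfg)
    write_count_matrix(counts, OUT / "counts.tsv")
    write_sample_sheet(sheet, OUT / "samples.tsv")
    write_gene_annotation(annot, OUT / "annotation.tsv")
    truth.table.to_csv(OUT / "truth.tsv", sep="\t", index=False, float_format="%.6g")

    fpkm = expression.compute_fpkm(counts, annot)
    ct = synthetic.simulate_qpcr(truth, fpkm, sheet, n_genes=12, ct_noise_sd=0.3, seed=SEED)
    ct.to_csv(OUT / "qpcr.tsv", sep="\t", index=False, float_format="%.4f")

    classes = truth.table["deg_class"].value_counts()
    print(f"wrote {len(counts.gene_ids)} genes x {len(counts.library_ids)} libraries to {OUT}")
    print("planted DEG classes:", dict(classes))
    print(f"guide gene: {truth.guide_gene}; planted MBW triad: {truth.mbw_triad}")


if __name__ == "__main__":
    main()
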