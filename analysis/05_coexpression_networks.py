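#!/usr/bin/env python
"""Pearson coexpression screens on the miR172OX/WT libraries.

Three layers: the ARF vs Aux/IAA pairwise screen (|PCC| > 0.90), the
structural-gene x TF network (PCC > 0.9 or < -0.8, stringent tier at
|PCC| >= 0.95), and the guide-gene subnetwork around the planted
structural guide with MBW (MYB-bHLH-WD40) triad detection. Exports
Cytoscape-ready SIF/TSV edge lists under results/.
"""

from pathlib import Path

import pandas as pd

from mir172tx import coexpression
from mir172tx.io_formats import (
    read_expression_matrix,
    read_gene_annotation,
    read_sample_sheet,
    write_edge_list,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    fpkm = read_expression_matrix(ROOT / "fpkm.tsv")
    sheet = read_sample_sheet(ROOT / "data" / "samples.tsv")
    annot = read_gene_annotation(ROOT / "data" / "annotation.tsv")
    truth = pd.read_csv(ROOT / "data" / "truth.tsv", sep="\t")
    retained = set((ROOT / "retained_genes.txt").read_text().split())
    exp1 = list(
        sheet.data.loc[sheet.data["genotype"].isin(["WT", "miR172OX"]), "library_id"]
    )

    arfs = [g for g in annot.genes_in_family("ARF") if g in retained]
    auxiaa = [g for g in annot.genes_in_family("Aux/IAA") if g in retained]
    pcc = coexpression.pairwise_pcc(fpkm, arfs, auxiaa, exp1)
    pairs = coexpression.screen_interaction_pairs(pcc)
    pd.DataFrame(pairs, columns=["gene_a", "gene_b", "pcc"]).to_csv(
        ROOT / "arf_auxiaa_pairs.tsv", sep="\t", index=False, float_format="%.6f"
    )
    print(f"ARF-Aux/IAA screen: {len(arfs)} ARFs x {len(auxiaa)} Aux/IAAs -> "
          f"{len(pairs)} pairs past |PCC| > 0.90")

    structural = [g for g in annot.genes_in_family("structural") if g in retained]
    tfs = [g for g in annot.genes_in_family("MYB", "bHLH", "WD40") if g in retained]
    net = coexpression.build_network(fpkm, structural, tfs, exp1, annot=annot)
    write_edge_list(net, ROOT / "network.tsv", "tsv")
    write_edge_list(net, ROOT / "network.sif", "sif")
    print(f"structural x TF network: {net.edge_counts()} edges")

    guide = truth.loc[truth["role"] == "guide", "gene_id"].iloc[0]
    candidates = sorted((set(structural) | set(tfs)) - {guide})
    sub = coexpression.guide_subnetwork(fpkm, guide, candidates, k=10, libraries=exp1, annot=annot)
    write_edge_list(sub, ROOT / "guide_subnetwork.tsv", "tsv")
    write_edge_list(sub, ROOT / "guide_subnetwork.sif", "sif")
    motifs = coexpression.find_mbw_motifs(sub, annot)
    pd.DataFrame(
        [(m.myb, m.bhlh, m.wd40, m.pcc_myb_bhlh, m.pcc_myb_wd40, m.pcc_bhlh_wd40) for m in motifs],
        columns=["myb", "bhlh", "wd40", "pcc_myb_bhlh", "pcc_myb_wd40", "pcc_bhlh_wd40"],
    ).to_csv(ROOT / "mbw_motifs.tsv", sep="\t", index=False, float_format="%.6f")
    print(f"guide subnetwork around {guide}: {len(sub.top_positive)} positive / "
          f"{len(sub.top_negative)} negative partners, {len(sub.edges)} edges; "
          f"{len(motifs)} stringent MBW motif(s)")
    if motifs:
        m = motifs[0]
        print(f"  strongest motif: {m.myb} (MYB) - {m.bhlh} (bHLH) - {m.wd40} (WD40), "
              f"weakest link |PCC| = {m.min_abs_pcc:.3f}")


if __name__ == "__main__":
    main()
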