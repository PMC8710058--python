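"""End-to-end orchestration: simulate (optional) -> FPKM -> QC -> DE ->
4-WPFB classification -> cross-dataset target DEGs -> coexpression
networks -> guide subnetwork -> MBW motifs -> qPCR concordance.

This module is glue: every computation lives in the stage modules.
Structured progress lines go to stderr; results go only to files, so two
runs with the same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coexpression, cross_compare, diffexpr, expression, qpcr, synthetic
from .io_formats import (
    CountMatrix,
    GeneAnnotation,
    SampleSheet,
    read_count_matrix,
    read_gene_annotation,
    read_sample_sheet,
    write_count_matrix,
    write_deg_table,
    write_edge_list,
    write_expression_matrix,
    write_gene_annotation,
    write_sample_sheet,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every knob of the analysis, with the study's defaults."""

    outdir: str = "pipeline_out"
    seed: int = 0
    simulate: bool = True
    # input paths, used when simulate is False
    counts_path: str | None = None
    samples_path: str | None = None
    annotation_path: str | None = None
    # thresholds
    fpkm_threshold: float = 2.0
    filter_before_de: bool = True
    padj_max: float = 0.05
    lfc_min: float = 1.0
    screen_pos_cutoff: float = 0.90
    screen_neg_cutoff: float = -0.90
    network_pos_cutoff: float = 0.9
    network_neg_cutoff: float = -0.8
    stringent_cutoff: float = 0.95
    guide_k: int = 10
    guide_gene: str | None = None  # None -> simulator's planted guide
    log_pseudocount: float = 1.0
    dead_zone: float = 0.0
    dispersion: str = "common"
    # qPCR simulation
    qpcr_n_genes: int = 12
    qpcr_ct_noise_sd: float = 0.3
    # simulator settings (forwarded to SimulationConfig; seed comes from above)
    sim: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.padj_max <= 1):
            raise ValueError(f"padj_max must be in (0, 1]: {self.padj_max}")
        if self.lfc_min < 0:
            raise ValueError("lfc_min must be non-negative")
        if self.fpkm_threshold < 0:
            raise ValueError("fpkm_threshold must be non-negative")
        for name in ("screen_pos_cutoff", "network_pos_cutoff", "stringent_cutoff"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]: {v}")
        for name in ("screen_neg_cutoff", "network_neg_cutoff"):
            v = getattr(self, name)
            if not (-1 <= v <= 0):
                raise ValueError(f"{name} must be in [-1, 0]: {v}")
        if self.guide_k < 1:
            raise ValueError("guide_k must be >= 1")
        if self.dead_zone < 0:
            raise ValueError("dead_zone must be non-negative")
        if not self.simulate:
            for p in (self.counts_path, self.samples_path, self.annotation_path):
                if p is None:
                    raise ValueError("counts/samples/annotation paths required when simulate is False")
                if not Path(p).exists():
                    raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _log(stage: str, t0: float, **counts) -> None:
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    print(f"[pipeline] {stage} {time.perf_counter() - t0:.2f}s {extras}", file=sys.stderr)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write all intermediate tables, return the summary."""
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": cfg.seed, "thresholds": {
        "fpkm_threshold": cfg.fpkm_threshold,
        "padj_max": cfg.padj_max,
        "lfc_min": cfg.lfc_min,
        "network_cutoffs": [cfg.network_pos_cutoff, cfg.network_neg_cutoff],
        "stringent_cutoff": cfg.stringent_cutoff,
    }}

    # --- inputs -----------------------------------------------------------
    t0 = time.perf_counter()
    truth = None
    if cfg.simulate:
        sim_cfg = synthetic.SimulationConfig(seed=cfg.seed, **cfg.sim)
        counts, sheet, annot, truth = synthetic.simulate_counts(sim_cfg)
        write_count_matrix(counts, out / "counts.tsv")
        write_sample_sheet(sheet, out / "samples.tsv")
        write_gene_annotation(annot, out / "annotation.tsv")
        truth.table.to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.6g")
    else:
        counts = read_count_matrix(cfg.counts_path)
        sheet = read_sample_sheet(cfg.samples_path)
        annot = read_gene_annotation(cfg.annotation_path)
    sheet.check_covers(counts)
    _log("inputs", t0, genes=len(counts.gene_ids), libraries=len(counts.library_ids))

    # --- expression -------------------------------------------------------
    t0 = time.perf_counter()
    fpkm = expression.compute_fpkm(counts, annot)
    write_expression_matrix(fpkm, out / "fpkm.tsv")
    retained = set(expression.filter_low_expression(fpkm, cfg.fpkm_threshold))
    qc = expression.replicate_qc(fpkm, sheet, pseudocount=cfg.log_pseudocount)
    qc.pairs.to_csv(out / "qc_pairs.tsv", sep="\t", index=False, float_format="%.6f")
    qc.summary.to_csv(out / "qc_summary.tsv", sep="\t", index=False, float_format="%.6f")
    summary["n_genes"] = len(counts.gene_ids)
    summary["n_retained"] = len(retained)
    summary["qc_r2_range"] = [round(v, 6) for v in qc.r2_range]
    _log("expression", t0, retained=len(retained))

    # --- differential expression -----------------------------------------
    t0 = time.perf_counter()
    test_counts = counts.subset_genes(retained) if cfg.filter_before_de else counts
    contrasts = diffexpr.contrasts_for_design(sheet, counts)
    results = {
        name: diffexpr.nb_wald_test(test_counts, c, dispersion=cfg.dispersion)
        for name, c in contrasts.items()
    }
    deg_rows = []
    degsets = {}
    for name, res in results.items():
        degsets[name] = diffexpr.call_degs(res, retained, cfg.padj_max, cfg.lfc_min)
        for g in sorted(degsets[name].all):
            row = res.table.loc[g]
            deg_rows.append(
                (g, name, row["log2fc"], row["pvalue"], row["padj"],
                 "up" if g in degsets[name].up else "down")
            )
        res.table.to_csv(out / f"de_{name}.tsv", sep="\t", float_format="%.6g")
    write_deg_table(
        pd.DataFrame(deg_rows, columns=["gene_id", "contrast", "log2fc", "pvalue", "padj", "direction"]),
        out / "degs.tsv",
    )
    summary["deg_counts"] = {
        name: {"up": len(ds.up), "down": len(ds.down)} for name, ds in degsets.items()
    }
    _log("diffexpr", t0, contrasts=len(results))

    # --- 4-WPFB classification and cross-dataset target DEGs --------------
    t0 = time.perf_counter()
    tissue_names = [n for n in results if n.startswith("172vsWT_") and n.endswith("4")]
    tissue_results = {n: results[n] for n in tissue_names}
    per_tissue, combined_4wpfb = diffexpr.classify_multi_tissue(
        tissue_results, retained, cfg.padj_max, cfg.lfc_min
    )
    summary["n_4wpfb_degs"] = len(combined_4wpfb)
    summary["n_2wpfb_degs"] = len(degsets["172vsWT_WF2"].all) if "172vsWT_WF2" in degsets else 0

    target = None
    if "M9vsHF_WF4" in degsets:
        dir_a = diffexpr.assign_direction(per_tissue, tissue_results)
        dir_b = diffexpr.assign_direction(
            {"M9vsHF_WF4": degsets["M9vsHF_WF4"]}, {"M9vsHF_WF4": results["M9vsHF_WF4"]}
        )
        cls = cross_compare.classify_shared(
            combined_4wpfb, degsets["M9vsHF_WF4"].all, dir_a, dir_b
        )
        target = cross_compare.derive_target_degs(cls)
        pd.DataFrame(
            sorted((g, target.provenance[g]) for g in target.genes),
            columns=["gene_id", "provenance"],
        ).to_csv(out / "target_degs.tsv", sep="\t", index=False)
        summary["shared"] = {
            "n_shared": len(cls.shared),
            "n_same_direction": len(cls.same_direction),
            "n_opposite_direction": len(cls.opposite_direction),
            "n_a_specific": len(cls.a_specific),
            "n_b_specific": len(cls.b_specific),
        }
        summary["target_degs"] = {
            "n_total": len(target.genes),
            **target.count_by_provenance(),
        }
    _log("cross_compare", t0, target=0 if target is None else len(target.genes))

    # --- coexpression -----------------------------------------------------
    t0 = time.perf_counter()
    exp1_libs = [
        l for l in counts.library_ids
        if l in set(sheet.data.loc[sheet.data["genotype"].isin(["WT", "miR172OX"]), "library_id"])
    ]
    arfs = [g for g in annot.genes_in_family("ARF") if g in retained]
    auxiaa = [g for g in annot.genes_in_family("Aux/IAA") if g in retained]
    screen_pairs = []
    if arfs and auxiaa:
        pcc = coexpression.pairwise_pcc(fpkm, arfs, auxiaa, exp1_libs, cfg.log_pseudocount)
        screen_pairs = coexpression.screen_interaction_pairs(
            pcc, cfg.screen_pos_cutoff, cfg.screen_neg_cutoff
        )
    pd.DataFrame(screen_pairs, columns=["gene_a", "gene_b", "pcc"]).to_csv(
        out / "arf_auxiaa_pairs.tsv", sep="\t", index=False, float_format="%.6f"
    )
    summary["n_arf_auxiaa_pairs"] = len(screen_pairs)

    structural = [g for g in annot.genes_in_family("structural") if g in retained]
    tfs = [g for g in annot.genes_in_family("MYB", "bHLH", "WD40") if g in retained]
    net = coexpression.build_network(
        fpkm, structural, tfs, exp1_libs,
        cfg.network_pos_cutoff, cfg.network_neg_cutoff, cfg.stringent_cutoff, annot,
    )
    write_edge_list(net, out / "network.tsv", "tsv")
    write_edge_list(net, out / "network.sif", "sif")
    summary["network_edges"] = net.edge_counts()

    guide = cfg.guide_gene or (truth.guide_gene if truth is not None else None)
    motifs: list = []
    if guide is not None and guide in fpkm.data.index:
        candidates = sorted((set(structural) | set(tfs)) - {guide})
        sub = coexpression.guide_subnetwork(
            fpkm, guide, candidates, cfg.guide_k, exp1_libs,
            cfg.network_pos_cutoff, cfg.network_neg_cutoff, cfg.stringent_cutoff, annot,
        )
        write_edge_list(sub, out / "guide_subnetwork.tsv", "tsv")
        write_edge_list(sub, out / "guide_subnetwork.sif", "sif")
        motifs = coexpression.find_mbw_motifs(sub, annot)
        summary["guide"] = {
            "gene": guide,
            "n_top_positive": len(sub.top_positive),
            "n_top_negative": len(sub.top_negative),
            "edge_counts": {k: v for k, v in _edge_counts(sub).items()},
        }
    pd.DataFrame(
        [
            (m.myb, m.bhlh, m.wd40, m.pcc_myb_bhlh, m.pcc_myb_wd40, m.pcc_bhlh_wd40)
            for m in motifs
        ],
        columns=["myb", "bhlh", "wd40", "pcc_myb_bhlh", "pcc_myb_wd40", "pcc_bhlh_wd40"],
    ).to_csv(out / "mbw_motifs.tsv", sep="\t", index=False, float_format="%.6f")
    summary["n_mbw_motifs"] = len(motifs)
    _log("coexpression", t0, edges=len(net.edges), motifs=len(motifs))

    # --- qPCR concordance -------------------------------------------------
    t0 = time.perf_counter()
    if truth is not None:
        ct = synthetic.simulate_qpcr(
            truth, fpkm, sheet, cfg.qpcr_n_genes, cfg.qpcr_ct_noise_sd, seed=cfg.seed
        )
        ct.to_csv(out / "qpcr.tsv", sep="\t", index=False, float_format="%.4f")
        ref = ct.loc[ct["role"] == "reference", "gene_id"].iloc[0] if len(ct) else None
        if ref is not None and (ct["role"] == "target").any():
            rel = qpcr.ddct_from_table(ct, ref)
            rel["comparison"] = rel["tissue"] + rel["timepoint"].astype(str)
            seq = {}
            for name, res in results.items():
                if name.startswith("172vsWT_"):
                    seq[name.removeprefix("172vsWT_")] = res.table["log2fc"].to_dict()
            report = qpcr.concordance(rel, seq, cfg.dead_zone)
            report.points.to_csv(
                out / "qpcr_concordance.tsv", sep="\t", index=False, float_format="%.6f"
            )
            summary["qpcr"] = {
                "n_points": report.n_used,
                "concordant_fraction": None
                if report.concordant_fraction is None
                else round(report.concordant_fraction, 6),
            }
        else:
            summary["qpcr"] = {"n_points": 0, "concordant_fraction": None}
    _log("qpcr", t0)

    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary


def _edge_counts(net) -> dict[str, int]:
    out = {"standard": 0, "stringent": 0}
    for e in net.edges:
        out[e.tier] += 1
    return out
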