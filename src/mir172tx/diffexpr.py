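"""Per-contrast differential expression: a simplified negative-binomial
Wald test, BH correction, DEG calling, and the 4-WPFB multi-tissue rule.

The test follows the standard bulk RNA-seq recipe — median-of-ratios size
factors, per-group NB means on normalized counts, method-of-moments
dispersion, a Wald statistic on the log2 mean difference against a normal
reference — without shrinkage, independent filtering or outlier
replacement. By default the method-of-moments dispersion is stabilized
across genes (a trimmed mean of per-gene estimates), since the per-gene
estimator at 3-vs-3 has too few degrees of freedom to give the Wald
statistic its nominal level; ``dispersion="per-gene"`` keeps the raw
estimates.

DEGs use the strict thresholds padj < 0.05 and log2FC > 1 or < -1. At
4 WPFB a gene is a DEG as soon as one of the three tissue contrasts
(skin, flesh, core) qualifies; a gene may be up in one tissue and down in
another, and then counts in both per-tissue tallies but once in the
combined set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import trim_mean
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, SampleSheet

__all__ = [
    "Contrast",
    "DEResult",
    "DEGSet",
    "size_factors",
    "nb_wald_test",
    "adjust_bh",
    "call_degs",
    "classify_multi_tissue",
    "assign_direction",
    "contrasts_for_design",
]

_LN2 = math.log(2.0)
_DISPERSION_FLOOR = 1e-8


@dataclass
class Contrast:
    """Treatment vs control, each a (genotype, tissue, timepoint) group."""

    name: str
    treatment: tuple[str, str, int]
    control: tuple[str, str, int]
    treatment_libs: list[str]
    control_libs: list[str]

    def __post_init__(self) -> None:
        t, c = set(self.treatment_libs), set(self.control_libs)
        if t & c:
            raise ValueError(f"contrast {self.name}: overlapping library sets")
        if len(t) < 2 or len(c) < 2:
            raise ValueError(f"contrast {self.name}: each group needs >= 2 libraries")


@dataclass
class DEResult:
    """Per-gene log2FC (treatment over control), p, padj, group means."""

    contrast: str
    table: pd.DataFrame  # index gene_id; log2fc, pvalue, padj, mean_treatment, mean_control

    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]


@dataclass
class DEGSet:
    contrast: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.up & self.down:
            raise ValueError("a gene cannot be both up and down in one contrast")

    @property
    def all(self) -> set[str]:
        return self.up | self.down


def contrasts_for_design(sheet: SampleSheet, counts: CountMatrix) -> dict[str, Contrast]:
    """The study's five contrasts: WF@2 plus FS/FF/FC@4 (miR172OX vs WT)
    and M9 vs Hanfu WF@4. Only groups present with >= 2 replicates enter."""
    out: dict[str, Contrast] = {}
    have = set(counts.library_ids)

    def grab(genotype, tissue, tp):
        return [l for l in sheet.libraries_for(genotype, tissue, tp) if l in have]

    specs = [
        ("172vsWT_WF2", ("miR172OX", "WF", 2), ("WT", "WF", 2)),
        ("172vsWT_FS4", ("miR172OX", "FS", 4), ("WT", "FS", 4)),
        ("172vsWT_FF4", ("miR172OX", "FF", 4), ("WT", "FF", 4)),
        ("172vsWT_FC4", ("miR172OX", "FC", 4), ("WT", "FC", 4)),
        ("M9vsHF_WF4", ("M9", "WF", 4), ("Hanfu", "WF", 4)),
    ]
    for name, treat, ctrl in specs:
        t, c = grab(*treat), grab(*ctrl)
        if len(t) >= 2 and len(c) >= 2:
            out[name] = Contrast(name, treat, ctrl, t, c)
    return out


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios library size factors.

    Per-gene geometric means use only genes with no zero count; if none
    exist the factors cannot be estimated.
    """
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene with all-nonzero counts; cannot estimate size factors")
    logs = np.log(counts[nonzero].astype(float))
    log_geo = logs.mean(axis=1)
    return np.exp(np.median(logs - log_geo[:, None], axis=0))


def nb_wald_test(
    counts: CountMatrix,
    contrast: Contrast,
    pseudocount: float = 0.5,
    dispersion: str = "common",
) -> DEResult:
    """Simplified NB Wald test for one two-group contrast.

    log2FC is computed from normalized group means with ``pseudocount``
    added to each mean; the Wald SE uses the delta-method variance of a
    log2 NB mean, (1/mu + alpha)/n per group. All-zero genes get
    log2fc 0 and p-value 1.
    """
    if dispersion not in ("common", "per-gene"):
        raise ValueError(f"unknown dispersion mode: {dispersion!r}")
    libs = contrast.treatment_libs + contrast.control_libs
    sub = counts.subset_libraries(libs)
    raw = sub.counts.astype(float)
    sf = size_factors(sub.counts)
    norm = raw / sf[None, :]
    n_t = len(contrast.treatment_libs)
    n_c = len(contrast.control_libs)
    kt, kc = norm[:, :n_t], norm[:, n_t:]

    mt = kt.mean(axis=1)
    mc = kc.mean(axis=1)
    # pooled within-group variance, n_t + n_c - 2 df
    ss = ((kt - mt[:, None]) ** 2).sum(axis=1) + ((kc - mc[:, None]) ** 2).sum(axis=1)
    var_within = ss / max(n_t + n_c - 2, 1)
    mean_all = (kt.sum(axis=1) + kc.sum(axis=1)) / (n_t + n_c)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_gene = (var_within - mean_all) / np.square(mean_all)
    alpha_gene = np.where(np.isfinite(alpha_gene), alpha_gene, 0.0)
    if dispersion == "common":
        # equal-weight trimmed mean across well-measured genes: per-gene
        # moment estimates have near-constant variance once the mean is
        # large, and the light trim guards against coexpression-module
        # genes whose shared latent factor inflates within-group variance
        informative = mean_all > 5.0
        pool = alpha_gene[informative] if informative.any() else alpha_gene
        common = max(float(trim_mean(pool, 0.025)), _DISPERSION_FLOOR)
        alpha = np.full_like(alpha_gene, common)
    else:
        alpha = np.maximum(alpha_gene, _DISPERSION_FLOOR)

    mt_p, mc_p = mt + pseudocount, mc + pseudocount
    log2fc = np.log2(mt_p / mc_p)
    se = np.sqrt(((1.0 / mt_p + alpha) / n_t + (1.0 / mc_p + alpha) / n_c)) / _LN2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = log2fc / se
    from scipy.stats import norm as normal

    pvalue = 2.0 * normal.sf(np.abs(z))

    allzero = (raw == 0).all(axis=1)
    log2fc[allzero] = 0.0
    pvalue[allzero] = 1.0

    padj = adjust_bh(pvalue)
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "pvalue": pvalue,
            "padj": padj,
            "mean_treatment": mt,
            "mean_control": mc,
        },
        index=pd.Index(sub.gene_ids, name="gene_id"),
    )
    return DEResult(contrast=contrast.name, table=table)


def adjust_bh(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if not np.isfinite(p).all() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must be finite and in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    result: DEResult,
    retained: set[str] | None = None,
    padj_max: float = 0.05,
    lfc_min: float = 1.0,
) -> DEGSet:
    """Strict thresholds: padj < padj_max and log2fc > lfc_min or < -lfc_min."""
    t = result.table
    if retained is not None:
        t = t.loc[t.index.isin(set(retained))]
    sig = t["padj"] < padj_max
    up = set(t.index[sig & (t["log2fc"] > lfc_min)])
    down = set(t.index[sig & (t["log2fc"] < -lfc_min)])
    return DEGSet(contrast=result.contrast, up=up, down=down)


def classify_multi_tissue(
    results: dict[str, DEResult],
    retained: set[str] | None = None,
    padj_max: float = 0.05,
    lfc_min: float = 1.0,
) -> tuple[dict[str, DEGSet], set[str]]:
    """Per-tissue DEG sets plus their combined union (the 4-WPFB rule).

    A gene qualifying in any tissue contrast is a combined DEG; a gene up
    in one tissue and down in another appears in both per-tissue sets but
    once in the combined set.
    """
    per_tissue = {
        name: call_degs(res, retained, padj_max, lfc_min) for name, res in results.items()
    }
    combined: set[str] = set()
    for ds in per_tissue.values():
        combined |= ds.all
    return per_tissue, combined


def assign_direction(
    degsets: dict[str, DEGSet], results: dict[str, DEResult]
) -> dict[str, str]:
    """One overall up/down per DEG across a dataset's contrasts.

    The direction is the sign of the largest-|log2FC| among the contrasts
    where the gene qualifies; an exact tie in |log2FC| resolves to "up".
    """
    genes: set[str] = set()
    for ds in degsets.values():
        genes |= ds.all
    out: dict[str, str] = {}
    for g in genes:
        lfcs = [
            float(results[name].table.at[g, "log2fc"])
            for name, ds in degsets.items()
            if g in ds.all
        ]
        best = max(abs(x) for x in lfcs)
        at_best = [x for x in lfcs if abs(x) == best]
        out[g] = "up" if any(x >= 0 for x in at_best) else "down"
    return out


def direction_for_gene(direction_map: dict[str, str], gene: str) -> str:
    if gene not in direction_map:
        raise KeyError(f"gene {gene!r} is not in any DEG set of this dataset")
    return direction_map[gene]
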