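"""Synthetic study generator.

Emulates the two-experiment apple fruit design at desk scale:

* experiment 1 — miR172-overexpressing 'Royal Gala' (miR172OX) vs wild
  type, whole fruit at 2 weeks post full bloom (WPFB) plus fruit skin,
  flesh and core at 4 WPFB, 3 biological replicates each (24 libraries);
* experiment 2 — small-fruited 'M9' vs large-fruited 'Hanfu', whole
  fruit at 4 WPFB, 3 replicates each (6 libraries).

Counts are negative binomial with mean ``mu_g * s_j`` (library size
factor ``s_j`` log-normal) and fixed dispersion ``alpha`` (variance
``mu + alpha*mu^2``). Differential expression is planted as log2-scale
mean shifts in the treatment genotypes; coexpression modules are planted
through a shared latent log-normal factor added to the log-mean, which
keeps counts integer and marginally NB. One module carries a
MYB/bHLH/WD40 triad plus a "structural" guide gene as a positive control
for the regulatory-motif search.

The full output is a pure function of :class:`SimulationConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import polygamma

from .io_formats import CountMatrix, ExpressionMatrix, GeneAnnotation, SampleSheet

__all__ = ["SimulationConfig", "PlantedTruth", "simulate_counts", "simulate_qpcr",
           "expression_ratio"]

LN2SQ = math.log(2) ** 2

# DEG classes
NULL = "null"
MIR172_SPECIFIC = "mir172_specific"
SHARED_SAME = "shared_same"
SHARED_OPPOSITE = "shared_opposite"


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    ``frac_*`` are the planted DEG class fractions; they must sum to at
    most 1. ``module_rho`` is the target pairwise Pearson correlation of
    log2 expression within a planted module. ``baseline_log2_sd`` sets
    the spread of per-gene baseline means around ``baseline_mean``
    (log2-normal; 0 gives every gene the same expected count).
    """

    n_genes: int = 5000
    baseline_mean: float = 200.0
    baseline_log2_sd: float = 2.0
    nb_dispersion: float = 0.1
    lfc_magnitude: float = 2.0
    frac_mir172_specific: float = 0.06
    frac_shared_same: float = 0.02
    frac_shared_opposite: float = 0.01
    n_modules: int = 3
    module_size: int = 20
    module_rho: float = 0.9
    libsize_log_sd: float = 0.2
    length_min: int = 500
    length_max: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = (
            self.frac_mir172_specific,
            self.frac_shared_same,
            self.frac_shared_opposite,
        )
        if any(f < 0 for f in fracs):
            raise ValueError("DEG fractions must be non-negative")
        if sum(fracs) > 1:
            raise ValueError("DEG fractions sum to more than 1")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not (0 < self.module_rho < 1):
            raise ValueError("module_rho must be in (0, 1)")


@dataclass
class PlantedTruth:
    """Ground truth emitted alongside the counts.

    ``table`` has one row per gene: class label, per-experiment direction
    (up/down/none, treatment over control), module_id (0 = none), family,
    the gene's baseline mean. ``guide_gene`` / ``mbw_triad`` identify the
    planted positive controls for the guide-gene and motif searches.
    """

    table: pd.DataFrame
    guide_gene: str | None = None
    mbw_triad: tuple[str, str, str] | None = None
    config: SimulationConfig | None = None

    def genes_in_class(self, label: str) -> list[str]:
        return list(self.table.loc[self.table["deg_class"] == label, "gene_id"])

    def module_members(self, module_id: int) -> list[str]:
        return list(self.table.loc[self.table["module_id"] == module_id, "gene_id"])

    def direction(self, gene_id: str, experiment: int) -> str:
        col = "dir_exp1" if experiment == 1 else "dir_exp2"
        return self.table.set_index("gene_id").loc[gene_id, col]


def _library_layout() -> pd.DataFrame:
    """The 30-library study design (24 exp-1 + 6 exp-2 libraries)."""
    rows = []
    for genotype in ("WT", "miR172OX"):
        for tissue, tp in (("WF", 2), ("FS", 4), ("FF", 4), ("FC", 4)):
            for rep in (1, 2, 3):
                rows.append((f"{genotype}_{tissue}{tp}_r{rep}", genotype, tissue, tp, rep))
    for genotype in ("Hanfu", "M9"):
        for rep in (1, 2, 3):
            rows.append((f"{genotype}_WF4_r{rep}", genotype, "WF", 4, rep))
    return pd.DataFrame(
        rows, columns=["library_id", "genotype", "tissue", "timepoint", "replicate"]
    )


def simulate_counts(
    config: SimulationConfig,
) -> tuple[CountMatrix, SampleSheet, GeneAnnotation, PlantedTruth]:
    """Draw one synthetic study; identical config (incl. seed) => identical output."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]
    layout = _library_layout()
    libs = list(layout["library_id"])
    n_lib = len(libs)

    is_treat1 = (layout["genotype"] == "miR172OX").to_numpy()  # exp 1 treatment
    is_treat2 = (layout["genotype"] == "M9").to_numpy()        # exp 2 treatment

    # per-gene baselines and lengths
    mu0 = cfg.baseline_mean * np.exp2(rng.normal(0.0, cfg.baseline_log2_sd, n))
    lengths = rng.integers(cfg.length_min, cfg.length_max + 1, size=n)

    # class assignment on a shuffled gene order
    order = rng.permutation(n)
    n_spec = round(cfg.frac_mir172_specific * n)
    n_same = round(cfg.frac_shared_same * n)
    n_opp = round(cfg.frac_shared_opposite * n)
    deg_class = np.full(n, NULL, dtype=object)
    deg_class[order[:n_spec]] = MIR172_SPECIFIC
    deg_class[order[n_spec : n_spec + n_same]] = SHARED_SAME
    deg_class[order[n_spec + n_same : n_spec + n_same + n_opp]] = SHARED_OPPOSITE

    # planted log2 effects per experiment
    sign = rng.choice([-1.0, 1.0], size=n)
    beta1 = np.zeros(n)
    beta2 = np.zeros(n)
    m_spec = deg_class == MIR172_SPECIFIC
    m_same = deg_class == SHARED_SAME
    m_opp = deg_class == SHARED_OPPOSITE
    beta1[m_spec | m_same | m_opp] = cfg.lfc_magnitude * sign[m_spec | m_same | m_opp]
    beta2[m_same] = beta1[m_same]
    beta2[m_opp] = -beta1[m_opp]

    # modules among null genes; module genes get a well-expressed floor so
    # the latent-factor calibration (delta method) is accurate
    module_id = np.zeros(n, dtype=int)
    null_pool = order[n_spec + n_same + n_opp :]
    needed = cfg.n_modules * cfg.module_size
    if needed > len(null_pool):
        raise ValueError("not enough null genes for the requested modules")
    for m in range(cfg.n_modules):
        members = null_pool[m * cfg.module_size : (m + 1) * cfg.module_size]
        module_id[members] = m + 1
    in_module = module_id > 0
    # module genes sit in a narrow, well-expressed band: keeps the latent
    # factor's delta-method calibration accurate and prevents a handful of
    # huge module genes from swinging library totals (which would couple
    # every other gene's FPKM to the module)
    mu0[in_module] = np.clip(mu0[in_module], cfg.baseline_mean, 4.0 * cfg.baseline_mean)

    # family labels: module genes cycle through network-relevant families
    # (module 1 leads with the guide + MBW triad); a sprinkle of ARF and
    # Aux/IAA labels outside modules feeds the pairwise interaction screen
    family = np.full(n, "none", dtype=object)
    role = np.full(n, "none", dtype=object)
    module_cycle = ["ARF", "Aux/IAA", "structural", "MYB", "bHLH", "none"]
    guide_gene = None
    mbw_triad = None
    for m in range(1, cfg.n_modules + 1):
        members = [i for i in null_pool if module_id[i] == m]
        if m == 1 and len(members) >= 4:
            family[members[0]] = "structural"
            family[members[1]] = "MYB"
            family[members[2]] = "bHLH"
            family[members[3]] = "WD40"
            role[members[0]] = "guide"
            role[members[1]] = role[members[2]] = role[members[3]] = "mbw"
            guide_gene = gene_ids[members[0]]
            mbw_triad = (gene_ids[members[1]], gene_ids[members[2]], gene_ids[members[3]])
            rest = members[4:]
        else:
            rest = members
        for k, i in enumerate(rest):
            family[i] = module_cycle[k % len(module_cycle)]
    non_module_null = [i for i in null_pool if module_id[i] == 0]
    for k, i in enumerate(non_module_null[: min(20, len(non_module_null))]):
        family[i] = "ARF" if k % 2 == 0 else "Aux/IAA"

    # latent module factors: shared z per (module, library); per-gene loading
    # calibrated so within-module log2-expression correlation ~ module_rho
    z = rng.normal(0.0, 1.0, size=(cfg.n_modules, n_lib))
    if cfg.n_modules > 0:
        if cfg.n_modules >= n_lib:
            raise ValueError("more modules than libraries")
        # centre, orthogonalize and standardize the latent factors so the
        # planted modules are exactly uncorrelated with each other and each
        # factor has unit variance across libraries — with only 30
        # libraries, raw Gaussian draws would leave chance inter-module
        # correlations of +-0.3 and muddy the ground truth
        z = z - z.mean(axis=1, keepdims=True)
        q, _ = np.linalg.qr(z.T)
        z = q.T[: cfg.n_modules] * math.sqrt(n_lib)
    loading = np.zeros(n)
    if cfg.n_modules > 0:
        # log2-scale NB noise: trigamma(1/alpha) for the gamma mixing layer
        # plus the Poisson layer's E[1/lambda] (delta method alone runs ~5% low)
        a = cfg.nb_dispersion
        if a < 0.5:
            sigma_e2 = (polygamma(1, 1.0 / a) + 1.0 / (mu0 * (1.0 - a))) / LN2SQ
        else:  # Poisson-layer correction diverges; fall back to delta method
            sigma_e2 = (1.0 / mu0 + a) / LN2SQ
        rho = cfg.module_rho
        loading[in_module] = np.sqrt(rho / (1.0 - rho) * sigma_e2[in_module])

    # library size factors, mean 1
    s = np.exp(rng.normal(-0.5 * cfg.libsize_log_sd**2, cfg.libsize_log_sd, n_lib))

    log2_mu = (
        np.log2(mu0)[:, None]
        + np.outer(beta1, is_treat1.astype(float))
        + np.outer(beta2, is_treat2.astype(float))
    )
    for m in range(cfg.n_modules):
        members = module_id == m + 1
        log2_mu[members] += loading[members, None] * z[m][None, :]
    mu = np.exp2(log2_mu) * s[None, :]

    alpha = cfg.nb_dispersion
    # numpy NB: n successes, p; mean = n(1-p)/p  =>  n = 1/alpha, p = 1/(1+alpha*mu)
    counts = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))

    cm = CountMatrix(pd.DataFrame(counts.astype(np.int64), index=gene_ids, columns=libs))
    sheet = SampleSheet(layout.copy())
    annot = GeneAnnotation(
        pd.DataFrame(
            {"gene_id": gene_ids, "length_bp": lengths.astype(int), "family": family}
        )
    )
    dir_label = np.where(sign > 0, "up", "down")
    truth = PlantedTruth(
        table=pd.DataFrame(
            {
                "gene_id": gene_ids,
                "deg_class": deg_class,
                "dir_exp1": np.where(beta1 != 0, dir_label, "none"),
                "dir_exp2": np.where(
                    beta2 != 0, np.where(beta2 > 0, "up", "down"), "none"
                ),
                "module_id": module_id,
                "family": family,
                "role": role,
                "baseline_mean": mu0,
            }
        ),
        guide_gene=guide_gene,
        mbw_triad=mbw_triad,
        config=cfg,
    )
    return cm, sheet, annot, truth


# ---------------------------------------------------------------------------
# qPCR simulation

_CT_ANCHOR_TARGET = 25.0
_CT_ANCHOR_REF = 18.0
_EPS = 0.01  # FPKM pseudocount inside the Ct transform


def _pick_reference_gene(truth: PlantedTruth) -> str:
    t = truth.table
    ok = (t["deg_class"] == NULL) & (t["module_id"] == 0)
    if not ok.any():
        raise ValueError("no null, module-free gene available as qPCR reference")
    return t.loc[ok, "gene_id"].iloc[0]


def simulate_qpcr(
    truth: PlantedTruth,
    expr: ExpressionMatrix,
    sheet: SampleSheet,
    n_genes: int = 12,
    ct_noise_sd: float = 0.3,
    seed: int = 0,
    reference_gene: str | None = None,
) -> pd.DataFrame:
    """Generate a Ct table for selected planted DEGs plus a reference gene.

    Ct values are reference-anchored ``-log2`` relative expression plus
    Gaussian noise, with triplicate technical reps per library. Columns:
    gene_id, library_id, genotype, tissue, timepoint, tech_rep, ct, role.
    With ``ct_noise_sd=0`` the 2^-ddCt recomputed from the table inverts
    to the geometric-mean expression ratio exactly.
    """
    rng = np.random.default_rng(seed)
    ref = reference_gene or _pick_reference_gene(truth)
    t = truth.table.set_index("gene_id")
    if t.loc[ref, "deg_class"] != NULL:
        raise ValueError(f"reference gene {ref!r} is a planted DEG")

    candidates = sorted(truth.genes_in_class(MIR172_SPECIFIC))
    selected = candidates[:n_genes]
    rows = []
    # qPCR runs on the experiment-1 (miR172OX/WT) libraries
    meta = sheet.data[sheet.data["genotype"].isin(["WT", "miR172OX"])]
    vals = expr.data
    for gene, role in [(ref, "reference")] + [(g, "target") for g in selected]:
        for _, lib in meta.iterrows():
            lid = lib["library_id"]
            if role == "reference":
                base = _CT_ANCHOR_REF
            else:
                rel = (vals.at[gene, lid] + _EPS) / (vals.at[ref, lid] + _EPS)
                base = _CT_ANCHOR_TARGET - math.log2(rel)
            for tr in (1, 2, 3):
                rows.append(
                    (
                        gene,
                        lid,
                        lib["genotype"],
                        lib["tissue"],
                        int(lib["timepoint"]),
                        tr,
                        base + rng.normal(0.0, ct_noise_sd),
                        role,
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "library_id",
            "genotype",
            "tissue",
            "timepoint",
            "tech_rep",
            "ct",
            "role",
        ],
    )


def expression_ratio(
    expr: ExpressionMatrix,
    gene: str,
    reference_gene: str,
    treatment_libs: list[str],
    control_libs: list[str],
) -> float:
    """Geometric-mean ratio of reference-normalized expression, treatment/control.

    This is the quantity the 2^-ddCt statistic estimates when Ct values are
    exact; used as the noiseless-inversion oracle for the qPCR simulator.
    """
    vals = expr.data

    def mean_log2_rel(libs):
        return float(
            np.mean(
                [
                    math.log2(
                        (vals.at[gene, l] + _EPS) / (vals.at[reference_gene, l] + _EPS)
                    )
                    for l in libs
                ]
            )
        )

    return 2.0 ** (mean_log2_rel(treatment_libs) - mean_log2_rel(control_libs))
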