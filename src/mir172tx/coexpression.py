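"""Pearson-correlation coexpression analysis.

Four screens built on the same primitive — the sample Pearson correlation
of per-library log2(FPKM + 1) profiles:

* a pairwise interaction screen (ARF vs Aux/IAA) at |PCC| > 0.90;
* a structural-gene vs transcription-factor network at PCC > 0.9 or
  < -0.8, with a stringent edge tier at |PCC| >= 0.95;
* a guide-gene subnetwork: the top-k positively and top-k negatively
  coexpressed candidates around one gene of known function, with induced
  edges tiered at the stringent cutoff;
* detection of MYB–bHLH–WD40 (MBW) triads whose three pairwise edges are
  all stringent — the signature of the ternary complex regulating
  flavonoid biosynthesis.

Genes with constant expression have an undefined correlation; they are
reported as missing and never rank or form edges. All top-k and sort
operations break ties by lexicographic gene ID so outputs are
bit-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, GeneAnnotation

__all__ = [
    "CorrelationEdge",
    "CoexpressionNetwork",
    "GuideSubnetwork",
    "MBWMotif",
    "pairwise_pcc",
    "screen_interaction_pairs",
    "build_network",
    "guide_subnetwork",
    "find_mbw_motifs",
]

STANDARD = "standard"
STRINGENT = "stringent"


@dataclass
class CorrelationEdge:
    gene_a: str
    gene_b: str
    pcc: float
    tier: str = STANDARD

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-loop on {self.gene_a!r}")
        if abs(self.pcc) > 1 + 1e-12:
            raise ValueError("|pcc| cannot exceed 1")
        if self.gene_a > self.gene_b:  # canonical undirected ordering
            self.gene_a, self.gene_b = self.gene_b, self.gene_a

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass
class CoexpressionNetwork:
    edges: list[CorrelationEdge]
    families: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for e in self.edges:
            if e.key in seen:
                raise ValueError(f"duplicate edge {e.key}")
            seen.add(e.key)

    @property
    def nodes(self) -> set[str]:
        return {g for e in self.edges for g in e.key}

    def edge_counts(self) -> dict[str, int]:
        out = {STANDARD: 0, STRINGENT: 0}
        for e in self.edges:
            out[e.tier] += 1
        return out


@dataclass
class GuideSubnetwork:
    guide: str
    top_positive: list[str]  # ranked, most positive first
    top_negative: list[str]  # ranked, most negative first
    edges: list[CorrelationEdge]
    families: dict[str, str] = field(default_factory=dict)

    @property
    def members(self) -> list[str]:
        return [self.guide] + self.top_positive + self.top_negative


@dataclass
class MBWMotif:
    myb: str
    bhlh: str
    wd40: str
    pcc_myb_bhlh: float
    pcc_myb_wd40: float
    pcc_bhlh_wd40: float

    @property
    def min_abs_pcc(self) -> float:
        return min(
            abs(self.pcc_myb_bhlh), abs(self.pcc_myb_wd40), abs(self.pcc_bhlh_wd40)
        )


def _log_profiles(
    expr: ExpressionMatrix, genes: list[str], libraries: list[str] | None, pseudocount: float
) -> pd.DataFrame:
    libs = list(libraries) if libraries is not None else expr.library_ids
    if len(libs) < 3:
        raise ValueError("need at least 3 libraries for a Pearson correlation")
    missing = [g for g in genes if g not in expr.data.index]
    if missing:
        raise KeyError(f"genes not in expression matrix: {missing[:5]}")
    return np.log2(expr.data.loc[genes, libs].astype(float) + pseudocount)


def pairwise_pcc(
    expr: ExpressionMatrix,
    set_x: list[str],
    set_y: list[str],
    libraries: list[str] | None = None,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Sample Pearson r between every x-gene and y-gene on log2(FPKM+pc).

    Constant-expression genes yield NaN (undefined correlation), never 0.
    """
    x = _log_profiles(expr, list(set_x), libraries, pseudocount).to_numpy()
    y = _log_profiles(expr, list(set_y), libraries, pseudocount).to_numpy()
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xs = np.sqrt((xc**2).sum(axis=1))
    ys = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc.T) / np.outer(xs, ys)
    r[~np.isfinite(r)] = np.nan
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=list(set_x), columns=list(set_y))


def screen_interaction_pairs(
    pcc: pd.DataFrame, pos_cutoff: float = 0.90, neg_cutoff: float = -0.90
) -> list[tuple[str, str, float]]:
    """Pairs with pcc > pos_cutoff or pcc < neg_cutoff (strict), sorted by
    |pcc| descending then lexicographic IDs; symmetric duplicates removed."""
    hits: dict[tuple[str, str], float] = {}
    for gx in pcc.index:
        for gy in pcc.columns:
            if gx == gy:
                continue
            r = pcc.at[gx, gy]
            if pd.isna(r):
                continue
            if r > pos_cutoff or r < neg_cutoff:
                key = (gx, gy) if gx < gy else (gy, gx)
                hits[key] = float(r)
    return sorted(
        [(a, b, r) for (a, b), r in hits.items()],
        key=lambda t: (-abs(t[2]), t[0], t[1]),
    )


def build_network(
    expr: ExpressionMatrix,
    structural: list[str],
    tfs: list[str],
    libraries: list[str] | None = None,
    pos_cutoff: float = 0.9,
    neg_cutoff: float = -0.8,
    stringent: float = 0.95,
    annot: GeneAnnotation | None = None,
) -> CoexpressionNetwork:
    """Structural-gene x TF network with asymmetric cutoffs.

    An edge exists when pcc > pos_cutoff or pcc < neg_cutoff; its tier is
    stringent when |pcc| >= ``stringent`` (inclusive), else standard.
    """
    pcc = pairwise_pcc(expr, list(structural), list(tfs), libraries)
    edges: dict[tuple[str, str], CorrelationEdge] = {}
    for gs in pcc.index:
        for gt in pcc.columns:
            if gs == gt:
                continue
            r = pcc.at[gs, gt]
            if pd.isna(r):
                continue
            if r > pos_cutoff or r < neg_cutoff:
                e = CorrelationEdge(
                    gs, gt, float(r), STRINGENT if abs(r) >= stringent else STANDARD
                )
                edges[e.key] = e
    fams = annot.families() if annot is not None else {}
    ordered = [edges[k] for k in sorted(edges)]
    nodes = {g for e in ordered for g in e.key}
    return CoexpressionNetwork(
        edges=ordered, families={g: fams.get(g, "none") for g in nodes}
    )


def guide_subnetwork(
    expr: ExpressionMatrix,
    guide: str,
    candidates: list[str],
    k: int = 10,
    libraries: list[str] | None = None,
    pos_cutoff: float = 0.9,
    neg_cutoff: float = -0.8,
    stringent: float = 0.95,
    annot: GeneAnnotation | None = None,
) -> GuideSubnetwork:
    """Top-k positively and top-k negatively coexpressed genes around a guide.

    Candidates are ranked by signed pcc with the guide within their sign
    group (ties to the lexicographically smaller ID); the guide itself is
    excluded from the candidate pool. Guide–member edges are always part
    of the subnetwork; member–member edges enter at the standard network
    cutoffs. Every induced edge is tiered stringent at |pcc| >=
    ``stringent``.
    """
    cand = sorted({c for c in candidates if c != guide})
    guide_profile = _log_profiles(expr, [guide], libraries, 1.0).to_numpy()
    if np.ptp(guide_profile) == 0:
        raise ValueError(f"guide gene {guide!r} has constant expression")
    scores: dict[str, float] = {}
    if cand:
        pcc_guide = pairwise_pcc(expr, [guide], cand, libraries)
        for c in cand:
            r = pcc_guide.at[guide, c]
            if not pd.isna(r):
                scores[c] = float(r)
    pos = sorted((c for c in scores if scores[c] > 0), key=lambda c: (-scores[c], c))[:k]
    neg = sorted((c for c in scores if scores[c] < 0), key=lambda c: (scores[c], c))[:k]

    members = [guide] + pos + neg
    full = pairwise_pcc(expr, members, members, libraries) if len(members) > 1 else None
    edges: dict[tuple[str, str], CorrelationEdge] = {}
    for a, b in itertools.combinations(members, 2):
        r = full.at[a, b]
        if pd.isna(r):
            continue
        r = float(r)
        keep = (guide in (a, b)) or (r > pos_cutoff or r < neg_cutoff)
        if keep:
            e = CorrelationEdge(a, b, r, STRINGENT if abs(r) >= stringent else STANDARD)
            edges[e.key] = e
    fams = annot.families() if annot is not None else {}
    return GuideSubnetwork(
        guide=guide,
        top_positive=pos,
        top_negative=neg,
        edges=[edges[key] for key in sorted(edges)],
        families={g: fams.get(g, "none") for g in members},
    )


def find_mbw_motifs(
    net: CoexpressionNetwork | GuideSubnetwork,
    annot: GeneAnnotation | None = None,
) -> list[MBWMotif]:
    """All MYB/bHLH/WD40 triads whose three pairwise edges are stringent.

    Family labels come from ``annot`` when given, else from the network's
    own annotations. Motifs are sorted by minimum |pcc| descending, then
    by gene IDs.
    """
    fams = annot.families() if annot is not None else dict(net.families)
    g = nx.Graph()
    for e in net.edges:
        if e.tier == STRINGENT:
            g.add_edge(e.gene_a, e.gene_b, pcc=e.pcc)
    by_family: dict[str, list[str]] = {"MYB": [], "bHLH": [], "WD40": []}
    for node in g.nodes:
        fam = fams.get(node)
        if fam in by_family:
            by_family[fam].append(node)
    motifs: list[MBWMotif] = []
    for myb in by_family["MYB"]:
        for bhlh in by_family["bHLH"]:
            if not g.has_edge(myb, bhlh):
                continue
            for wd in by_family["WD40"]:
                if g.has_edge(myb, wd) and g.has_edge(bhlh, wd):
                    motifs.append(
                        MBWMotif(
                            myb,
                            bhlh,
                            wd,
                            g[myb][bhlh]["pcc"],
                            g[myb][wd]["pcc"],
                            g[bhlh][wd]["pcc"],
                        )
                    )
    motifs.sort(key=lambda m: (-m.min_abs_pcc, m.myb, m.bhlh, m.wd40))
    return motifs
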