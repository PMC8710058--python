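"""Tabular I/O and the pipeline's core data containers.

Every file the pipeline reads or writes is TSV (tab-separated, UTF-8,
``.`` decimal) — one dialect, bit-exact round trips, no autodetection.
Gene and library order is preserved as read; downstream code keys by ID,
never by position.

Containers wrap a pandas DataFrame and validate on construction; readers
never silently coerce — a malformed cell is a named, located error.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "GeneAnnotation",
    "ExpressionMatrix",
    "read_count_matrix",
    "write_count_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_gene_annotation",
    "write_gene_annotation",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_deg_table",
    "write_deg_table",
    "write_edge_list",
    "read_edge_list",
]

_INT_RE = re.compile(r"^\d+$")


def _check_unique(ids, kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} ID: {i!r}")
        seen.add(i)


@dataclass
class CountMatrix:
    """Integer read counts, genes (rows) x libraries (columns)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "library")
        arr = self.data.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (arr < 0).any():
            g, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at gene {self.data.index[g]!r}, "
                f"library {self.data.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset_libraries(self, library_ids: list[str]) -> "CountMatrix":
        missing = [l for l in library_ids if l not in self.data.columns]
        if missing:
            raise KeyError(f"libraries not in count matrix: {missing}")
        return CountMatrix(self.data[library_ids])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        keep = [g for g in self.data.index if g in set(gene_ids)]
        return CountMatrix(self.data.loc[keep])


@dataclass
class SampleSheet:
    """Library metadata: genotype, tissue, timepoint (WPFB), replicate.

    Groups are keyed by ``(genotype, tissue, timepoint)``; groups with a
    single replicate are recorded in :attr:`underreplicated` and must be
    excluded from differential-expression contrasts.
    """

    data: pd.DataFrame
    underreplicated: list[tuple] = field(default_factory=list)

    REQUIRED = ("library_id", "genotype", "tissue", "timepoint", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.data.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if len(self.data) == 0:
            raise ValueError("no libraries in sample sheet")
        _check_unique(self.data["library_id"], "library")
        if (self.data["replicate"].astype(int) < 1).any():
            raise ValueError("replicate indices must be positive")
        self.underreplicated = [
            key for key, n in self.group_sizes().items() if n < 2
        ]
        for key in self.underreplicated:
            warnings.warn(
                f"group {key} has a single replicate; excluded from contrasts",
                stacklevel=2,
            )

    @property
    def library_ids(self) -> list[str]:
        return list(self.data["library_id"])

    def group_sizes(self) -> dict[tuple, int]:
        sizes: dict[tuple, int] = {}
        for _, row in self.data.iterrows():
            key = (row["genotype"], row["tissue"], int(row["timepoint"]))
            sizes[key] = sizes.get(key, 0) + 1
        return sizes

    def libraries_for(self, genotype: str, tissue: str, timepoint: int) -> list[str]:
        m = (
            (self.data["genotype"] == genotype)
            & (self.data["tissue"] == tissue)
            & (self.data["timepoint"].astype(int) == int(timepoint))
        )
        return list(self.data.loc[m, "library_id"])

    def check_covers(self, counts: CountMatrix) -> None:
        """Every library in the count matrix must appear in the sheet."""
        known = set(self.library_ids)
        for lib in counts.library_ids:
            if lib not in known:
                raise ValueError(f"library {lib!r} in counts but absent from sample sheet")


@dataclass
class GeneAnnotation:
    """Per-gene effective transcript length (bp) and family label.

    Family labels (ARF, Aux/IAA, MYB, bHLH, WD40, structural, none, ...)
    drive the coexpression screens; ``length_bp`` drives FPKM.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for c in ("gene_id", "length_bp", "family"):
            if c not in self.data.columns:
                raise ValueError(f"annotation missing column: {c}")
        _check_unique(self.data["gene_id"], "gene")
        if (self.data["length_bp"].astype(int) <= 0).any():
            bad = self.data.loc[self.data["length_bp"].astype(int) <= 0, "gene_id"].iloc[0]
            raise ValueError(f"non-positive length for gene {bad!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data["gene_id"])

    def lengths_for(self, gene_ids: list[str]) -> np.ndarray:
        lut = dict(zip(self.data["gene_id"], self.data["length_bp"].astype(int)))
        missing = [g for g in gene_ids if g not in lut]
        if missing:
            raise ValueError(f"missing length for gene {missing[0]!r}")
        return np.array([lut[g] for g in gene_ids], dtype=float)

    def families(self) -> dict[str, str]:
        return dict(zip(self.data["gene_id"], self.data["family"]))

    def genes_in_family(self, *families: str) -> list[str]:
        fam = set(families)
        return list(self.data.loc[self.data["family"].isin(fam), "gene_id"])


@dataclass
class ExpressionMatrix:
    """FPKM values, genes x libraries, finite and non-negative."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "library")
        arr = self.data.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            g, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression at gene {self.data.index[g]!r}, "
                f"library {self.data.columns[j]!r}"
            )
        if (arr < 0).any():
            g, j = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative expression at gene {self.data.index[g]!r}, "
                f"library {self.data.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def library_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# readers / writers


def read_count_matrix(path) -> CountMatrix:
    """Read a gene x library count TSV (header = library IDs, col 1 = gene IDs).

    Any cell that is not a plain non-negative integer literal is a hard
    error naming its row and column; pre-rounded estimates are rejected,
    not floored.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    _check_unique(df.index, "gene")
    _check_unique(df.columns, "library")
    out = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for j, lib in enumerate(df.columns):
        col = raw[:, j]
        for i, cell in enumerate(col):
            if not _INT_RE.match(cell):
                raise ValueError(
                    f"non-integer or negative count {cell!r} at gene "
                    f"{df.index[i]!r}, library {lib!r}"
                )
        out[:, j] = col.astype(np.int64)
    return CountMatrix(pd.DataFrame(out, index=df.index, columns=df.columns))


def write_count_matrix(cm: CountMatrix, path) -> None:
    cm.data.to_csv(path, sep="\t", index_label="gene_id")


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if len(df) == 0:
        raise ValueError("no libraries in sample sheet")
    df["timepoint"] = df["timepoint"].astype(int)
    df["replicate"] = df["replicate"].astype(int)
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.data.to_csv(path, sep="\t", index=False)


def read_gene_annotation(path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    df["length_bp"] = df["length_bp"].astype(int)
    return GeneAnnotation(df)


def write_gene_annotation(annot: GeneAnnotation, path) -> None:
    annot.data.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df.astype(float))


def write_expression_matrix(em: ExpressionMatrix, path) -> None:
    em.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


def write_deg_table(rows: pd.DataFrame, path) -> None:
    """Write a DEG table (gene_id, contrast, log2fc, pvalue, padj, direction)."""
    cols = ["gene_id", "contrast", "log2fc", "pvalue", "padj", "direction"]
    missing = [c for c in cols if c not in rows.columns]
    if missing:
        raise ValueError(f"DEG table missing columns: {missing}")
    rows[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_deg_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "direction": str})
    return df


def write_edge_list(network, path, format: str = "tsv") -> None:
    """Export a coexpression network for Cytoscape.

    ``sif``: ``source pp target``, one edge per line, no header.
    ``tsv``: source, target, pcc (6 decimal places), tier, with header.
    """
    if format not in ("sif", "tsv"):
        raise ValueError(f"unknown edge-list format: {format!r}")
    with open(path, "w", encoding="utf-8") as fh:
        if format == "sif":
            for e in network.edges:
                fh.write(f"{e.gene_a} pp {e.gene_b}\n")
        else:
            fh.write("source\ttarget\tpcc\ttier\n")
            for e in network.edges:
                fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.pcc:.6f}\t{e.tier}\n")


def read_edge_list(path) -> list[tuple[str, str, float, str]]:
    """Read an edge-list TSV back to (source, target, pcc, tier) tuples."""
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str, "tier": str})
    return [
        (r.source, r.target, float(r.pcc), r.tier)
        for r in df.itertuples(index=False)
    ]
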