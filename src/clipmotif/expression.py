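"""Fold-change estimation and motif-conditioned expression binning.

A light stand-in fold-change estimator (median-of-ratios size factors, a
0.5 pseudocount, no shrinkage or testing) feeds the binning analyses;
externally computed differential-expression tables can be ingested instead.
Bins are summarised by their empirical CDF and median log2 fold change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .motifs import GeneMotifSummary

SIGNIFICANCE_PADJ = 0.05
SIGNIFICANCE_ABS_LFC = 1.0


@dataclass
class ExpressionTable:
    """Per-gene baseMean / log2FC (induced vs control), optional padj."""

    records: pd.DataFrame  # columns gene_id, baseMean, log2fc, padj (nullable)
    size_factors: pd.Series | None = None

    def significant(self) -> pd.DataFrame:
        """padj <= 0.05 and |log2FC| > 1; rows lacking padj are excluded."""
        df = self.records
        return df[
            (df["padj"].notna())
            & (df["padj"] <= SIGNIFICANCE_PADJ)
            & (df["log2fc"].abs() > SIGNIFICANCE_ABS_LFC)
        ]


@dataclass
class BinResult:
    label: str
    gene_ids: list[str]
    n: int
    median_lfc: float  # nan when the bin is empty
    cdf_points: list[tuple[float, float]]


@dataclass
class TileCell:
    position: int  # 1-7
    base: str
    median_lfc: float
    n: int


def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: median of count/geometric-mean ratios.

    The geometric-mean reference uses only genes with all-positive counts.
    """
    log_counts = np.log(counts.where(counts > 0))
    log_ref = log_counts.mean(axis=1)
    usable = log_counts.notna().all(axis=1)
    if not usable.any():
        raise ValueError("no gene has positive counts in every sample")
    log_ratios = log_counts.loc[usable].sub(log_ref[usable], axis=0)
    return np.exp(log_ratios.median(axis=0)).rename("size_factor")


def compute_log2fc(
    counts: pd.DataFrame,
    design: pd.DataFrame,
    pseudocount: float = 0.5,
) -> ExpressionTable:
    """baseMean and log2FC from a genes x samples count matrix.

    ``design`` has columns sample/condition with conditions "control" and
    "induced".  log2fc = log2((mean normalized induced + pc) /
    (mean normalized control + pc)).  All-zero genes are retained with
    baseMean 0 and log2fc 0.  No p-values are computed.
    """
    ctl = design.loc[design["condition"] == "control", "sample"].tolist()
    ind = design.loc[design["condition"] == "induced", "sample"].tolist()
    if len(ctl) < 2 or len(ind) < 2:
        raise ValueError("need >= 2 samples per condition")
    sf = size_factors_median_of_ratios(counts[ctl + ind])
    norm = counts[ctl + ind].div(sf, axis=1)
    base_mean = norm.mean(axis=1)
    mean_ctl = norm[ctl].mean(axis=1)
    mean_ind = norm[ind].mean(axis=1)
    lfc = np.log2((mean_ind + pseudocount) / (mean_ctl + pseudocount))
    lfc[(mean_ctl == 0) & (mean_ind == 0)] = 0.0
    records = pd.DataFrame(
        {
            "gene_id": counts.index,
            "baseMean": base_mean.to_numpy(),
            "log2fc": lfc.to_numpy(),
            "padj": np.nan,
        }
    )
    return ExpressionTable(records=records, size_factors=sf)


def ingest_de_table(path: str | Path) -> ExpressionTable:
    """Load an external DE table (gene_id, baseMean, log2FoldChange[, padj])."""
    df = pd.read_csv(path, sep="\t")
    for col in ("gene_id", "baseMean", "log2FoldChange"):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    records = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "baseMean": df["baseMean"].astype(float),
            "log2fc": df["log2FoldChange"].astype(float),
            "padj": df["padj"].astype(float) if "padj" in df.columns else np.nan,
        }
    )
    return ExpressionTable(records=records)


def write_de_table(table: ExpressionTable, path: str | Path) -> None:
    out = table.records.rename(columns={"log2fc": "log2FoldChange"})
    out.to_csv(path, sep="\t", index=False)


def cdf(values: Sequence[float]) -> list[tuple[float, float]]:
    """Empirical CDF as (value, cumulative fraction) steps; ties share a step."""
    vals = np.asarray(sorted(values), dtype=float)
    if vals.size == 0:
        raise ValueError("cdf of empty value set")
    uniq, counts = np.unique(vals, return_counts=True)
    fracs = np.cumsum(counts) / vals.size
    return list(zip(uniq.tolist(), fracs.tolist()))


def _bin_result(label: str, df: pd.DataFrame) -> BinResult:
    vals = df["log2fc"].to_numpy()
    return BinResult(
        label=label,
        gene_ids=df["gene_id"].tolist(),
        n=len(df),
        median_lfc=float(np.median(vals)) if len(vals) else float("nan"),
        cdf_points=cdf(vals) if len(vals) else [],
    )


def _filtered(expr: ExpressionTable, min_basemean: float) -> pd.DataFrame:
    df = expr.records
    return df[df["baseMean"] >= min_basemean].copy()


def _motif_count(s: GeneMotifSummary, count_space: str) -> int:
    if count_space == "region":
        return s.n_utr3
    if count_space == "sites":
        return s.n_in_clusters
    raise ValueError(f"unknown count_space {count_space!r}")


def bin_by_site_count(
    expr: ExpressionTable,
    summaries: Mapping[str, GeneMotifSummary],
    bound_genes: set[str] | None = None,
    min_basemean: float = 10.0,
    count_space: str = "region",
) -> list[BinResult]:
    """Bins {>=2 motifs, 1 motif, bound-without-motif, unbound}.

    Motif counts come from the 3'UTR (``count_space='region'``) or from
    within called clusters (``'sites'``).  ``bound_genes`` separates
    motif-free genes into bound vs unbound; when None, all motif-free genes
    fall into one "no_motif" bin.
    """
    df = _filtered(expr, min_basemean)
    bins: dict[str, list] = (
        {"ge2": [], "one": [], "bound_no_motif": [], "unbound": []}
        if bound_genes is not None
        else {"ge2": [], "one": [], "no_motif": []}
    )
    for _, row in df.iterrows():
        g = row["gene_id"]
        s = summaries.get(g)
        k = _motif_count(s, count_space) if s else 0
        if k >= 2:
            bins["ge2"].append(row)
        elif k == 1:
            bins["one"].append(row)
        elif bound_genes is not None:
            bins["bound_no_motif" if g in bound_genes else "unbound"].append(row)
        else:
            bins["no_motif"].append(row)
    return [
        _bin_result(label, pd.DataFrame(rows, columns=df.columns))
        for label, rows in bins.items()
    ]


def bin_by_region(
    expr: ExpressionTable,
    summaries: Mapping[str, GeneMotifSummary],
    min_basemean: float = 10.0,
) -> list[BinResult]:
    """Bins {utr3_ge2, utr3_1, cds, utr5, none}; region priority utr3 > cds > utr5."""
    df = _filtered(expr, min_basemean)
    bins: dict[str, list] = {
        "utr3_ge2": [],
        "utr3_1": [],
        "cds": [],
        "utr5": [],
        "none": [],
    }
    for _, row in df.iterrows():
        s = summaries.get(row["gene_id"])
        if s is None or s.n_total == 0:
            bins["none"].append(row)
        elif s.n_utr3 >= 2:
            bins["utr3_ge2"].append(row)
        elif s.n_utr3 == 1:
            bins["utr3_1"].append(row)
        elif s.n_cds >= 1:
            bins["cds"].append(row)
        else:
            bins["utr5"].append(row)
    return [
        _bin_result(label, pd.DataFrame(rows, columns=df.columns))
        for label, rows in bins.items()
    ]


def variant_tile(
    expr: ExpressionTable,
    summaries: Mapping[str, GeneMotifSummary],
    motif_len: int = 7,
    canonical: str = "ATGAATT",
    min_basemean: float = 10.0,
) -> tuple[list[TileCell], TileCell]:
    """The 21-cell single-substitution tolerance tile plus a canonical cell.

    Cell (position, base) holds the median log2FC of genes whose 3'UTR
    carries that variant and no canonical copy (exclusivity enforced
    upstream in the summaries); the canonical cell uses genes with >=1
    canonical 3'UTR copy.
    """
    df = _filtered(expr, min_basemean).set_index("gene_id")
    cells: list[TileCell] = []
    for pos in range(1, motif_len + 1):
        for base in "ACGT":
            if base == canonical[pos - 1]:
                continue
            label = f"pos{pos}{base}"
            vals = [
                df.loc[g, "log2fc"]
                for g, s in summaries.items()
                if s.variant_presence.get(label) and g in df.index
            ]
            cells.append(
                TileCell(
                    position=pos,
                    base=base,
                    median_lfc=float(np.median(vals)) if vals else float("nan"),
                    n=len(vals),
                )
            )
    canon_vals = [
        df.loc[g, "log2fc"]
        for g, s in summaries.items()
        if s.n_utr3 >= 1 and g in df.index
    ]
    canonical_cell = TileCell(
        position=0,
        base="canonical",
        median_lfc=float(np.median(canon_vals)) if canon_vals else float("nan"),
        n=len(canon_vals),
    )
    return cells, canonical_cell


def bins_to_frame(bins: Sequence[BinResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "label": [b.label for b in bins],
            "n": [b.n for b in bins],
            "median_lfc": [b.median_lfc for b in bins],
        }
    )
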