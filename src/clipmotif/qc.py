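"""Reproducibility and localization diagnostics.

XRPM (crosslinked reads per million) per gene, Spearman correlation across
libraries, metagene profiles on a normalized 5'UTR/CDS/3'UTR axis, and
region composition of called clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import Cluster
from .io_formats import AlignedRead, TranscriptAnnotation

logger = logging.getLogger(__name__)

REGION_ORDER = ("utr5", "cds", "utr3")
ALL_REGIONS = ("utr5", "cds", "utr3", "intron", "unannotated")


@dataclass
class GeneXrpm:
    gene_id: str
    crosslinked_reads: int
    xrpm: float


def xrpm_per_gene(
    reads: Sequence[AlignedRead],
    clusters: Sequence[Cluster],
    annotation: TranscriptAnnotation,
    universe: str = "sites",
) -> list[GeneXrpm]:
    """Crosslinked reads per million library crosslinked reads, per gene.

    A read is crosslinked when it carries >=1 T->C event.  With
    ``universe='sites'`` it must additionally overlap one of the gene's
    retained clusters; with ``'all'`` any crosslinked read counts toward the
    gene hosting its transcript.
    """
    cluster_ivals: dict[str, list[tuple[int, int, str]]] = {}
    for c in clusters:
        cluster_ivals.setdefault(c.reference_name, []).append(
            (c.start, c.end, c.gene_id)
        )
    counts: dict[str, int] = {}
    for r in reads:
        if not any(m.is_t2c for m in r.mismatches):
            continue
        if universe == "sites":
            for lo, hi, gene in cluster_ivals.get(r.reference_name, []):
                if r.start < hi and r.end > lo:
                    if gene:
                        counts[gene] = counts.get(gene, 0) + 1
                    break
        elif universe == "all":
            gene = annotation.gene_of.get(r.reference_name, "")
            if gene:
                counts[gene] = counts.get(gene, 0) + 1
        else:
            raise ValueError(f"unknown universe {universe!r}")
    total = sum(counts.values())
    if total == 0:
        logger.info("no crosslinked reads; all XRPM set to 0")
        return [GeneXrpm(g, 0, 0.0) for g in counts]
    return [
        GeneXrpm(g, n, n / total * 1e6) for g, n in sorted(counts.items())
    ]


def spearman_matrix(tables: Sequence[Sequence[GeneXrpm]]) -> pd.DataFrame:
    """Pairwise Spearman correlation over the union gene universe.

    Genes absent from a library are imputed as 0.  A constant vector makes
    its correlations undefined (NaN).
    """
    if len(tables) < 2:
        raise ValueError("need >= 2 libraries")
    genes = sorted({g.gene_id for t in tables for g in t})
    mat = np.zeros((len(genes), len(tables)))
    idx = {g: i for i, g in enumerate(genes)}
    for j, t in enumerate(tables):
        for g in t:
            mat[idx[g.gene_id], j] = g.xrpm
    n = len(tables)
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if np.ptp(mat[:, i]) == 0 or np.ptp(mat[:, j]) == 0:
                rho = np.nan
            else:
                rho = stats.spearmanr(mat[:, i], mat[:, j]).statistic
            out[i, j] = out[j, i] = rho
    labels = [f"lib{j + 1}" for j in range(n)]
    return pd.DataFrame(out, index=labels, columns=labels)


def metagene_profile(
    clusters: Sequence[Cluster],
    annotation: TranscriptAnnotation,
    bins_per_region: tuple[int, int, int] = (10, 30, 30),
) -> pd.DataFrame:
    """count_T2C-weighted density along a normalized 5'UTR/CDS/3'UTR axis.

    Each cluster contributes its count_T2C at its midpoint's normalized
    position within its host region; the three regions are concatenated with
    fixed bin widths and the profile is normalized to sum 1.
    """
    n_bins = sum(bins_per_region)
    density = np.zeros(n_bins)
    offsets = {
        "utr5": 0,
        "cds": bins_per_region[0],
        "utr3": bins_per_region[0] + bins_per_region[1],
    }
    nb = dict(zip(REGION_ORDER, bins_per_region))
    used = 0
    for c in clusters:
        if c.region not in offsets:
            continue
        bounds = annotation.region_bounds(c.reference_name, c.region)
        if bounds is None or bounds[1] <= bounds[0]:
            continue
        lo, hi = bounds
        mid = (c.start + c.end) / 2
        frac = min(max((mid - lo) / (hi - lo), 0.0), 1.0 - 1e-9)
        b = offsets[c.region] + int(frac * nb[c.region])
        density[b] += c.count_T2C
        used += 1
    if used == 0:
        logger.info("no annotated clusters; empty metagene profile")
        return pd.DataFrame(columns=["bin", "region", "density"])
    if density.sum() > 0:
        density = density / density.sum()
    region_col = (
        ["utr5"] * bins_per_region[0]
        + ["cds"] * bins_per_region[1]
        + ["utr3"] * bins_per_region[2]
    )
    return pd.DataFrame(
        {"bin": np.arange(n_bins), "region": region_col, "density": density}
    )


def region_composition(clusters: Sequence[Cluster]) -> dict[str, float]:
    """Fraction of clusters per region label, summing to 1."""
    out = {r: 0.0 for r in ALL_REGIONS}
    if not clusters:
        return out
    for c in clusters:
        out[c.region if c.region in out else "unannotated"] += 1
    return {r: v / len(clusters) for r, v in out.items()}
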