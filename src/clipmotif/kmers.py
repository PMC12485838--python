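"""K-mer proportion Z-score enrichment of cluster sequences.

Cluster sequences are compared against the <=200-nt flanking regions
upstream and downstream of each cluster: the cluster-side proportion X of
each k-mer (pooled over all cluster windows) is standardised against the
mean and standard deviation of the per-flank-region proportions,
Z = (X - mu) / sigma.  Sigma is the sample (n-1) standard deviation across
background regions by default; a binomial standard error is available as an
alternative for sensitivity checks.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .clusters import Cluster


@dataclass
class KmerStat:
    """One k-mer's cluster proportion, background stats and Z-score."""

    kmer: str
    x_cluster: float
    mu_bg: float
    sigma_bg: float
    z: float
    au_rich: bool = False
    atg_containing: bool = False
    sigma_zero: bool = False


def all_kmers(k: int) -> list[str]:
    return ["".join(p) for p in itertools.product("ACGT", repeat=k)]


def extract_background(
    clusters: Sequence[Cluster],
    reference: dict[str, str],
    flank: int = 200,
) -> list[str]:
    """Flanking sequences around each cluster, cluster-overlap excluded.

    For each cluster the <=flank-nt slice upstream of its start and
    downstream of its end is taken, clipped at transcript bounds; any part
    overlapping another cluster's interval is cut out, and each remaining
    contiguous piece is one background region.
    """
    by_ref: dict[str, list[tuple[int, int]]] = {}
    for c in clusters:
        by_ref.setdefault(c.reference_name, []).append((c.start, c.end))
    out: list[str] = []
    for c in clusters:
        seq = reference[c.reference_name]
        blocked = [iv for iv in by_ref[c.reference_name] if iv != (c.start, c.end)]
        for lo, hi in (
            (max(0, c.start - flank), c.start),
            (c.end, min(len(seq), c.end + flank)),
        ):
            for a, b in _subtract(lo, hi, blocked):
                out.append(seq[a:b])
    return [s for s in out if s]


def _subtract(
    lo: int, hi: int, blocked: list[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Pieces of [lo, hi) not covered by any blocked interval."""
    pieces = [(lo, hi)] if hi > lo else []
    for b_lo, b_hi in sorted(blocked):
        nxt = []
        for a, b in pieces:
            if b_hi <= a or b_lo >= b:
                nxt.append((a, b))
            else:
                if a < b_lo:
                    nxt.append((a, b_lo))
                if b_hi < b:
                    nxt.append((b_hi, b))
        pieces = nxt
    return pieces


def count_kmers(seqs: Sequence[str], k: int = 5) -> dict[str, int]:
    """Overlapping k-mer window counts over the full 4**k space.

    Windows containing non-ACGT characters are skipped.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = dict.fromkeys(all_kmers(k), 0)
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            w = seq[i: i + k]
            if w in counts:
                counts[w] += 1
    return counts


def _proportions(counts: dict[str, int], kmers: list[str]) -> np.ndarray:
    v = np.array([counts[m] for m in kmers], dtype=float)
    total = v.sum()
    return v / total if total > 0 else v


def kmer_zscores(
    cluster_seqs: Sequence[str],
    background_region_seqs: Sequence[str],
    k: int = 5,
    ddof: int = 1,
    sigma_mode: str = "regions",
) -> list[KmerStat]:
    """Z = (X - mu)/sigma per k-mer, sorted by Z descending.

    X is the pooled cluster-window proportion; mu and sigma are the mean and
    (n-1) standard deviation of per-background-region proportions.  K-mers
    with sigma == 0 are flagged (``sigma_zero``); their z is +/-inf when the
    cluster proportion departs from the constant background (certain
    enrichment/depletion, e.g. a k-mer wholly absent from background) and NaN
    when it matches, in which case they sort to the bottom, unranked.
    ``sigma_mode='binomial'`` replaces sigma with the binomial standard error
    sqrt(mu(1-mu)/W) over the pooled background window count W.
    """
    kmers = all_kmers(k)
    usable = [s for s in background_region_seqs if len(s) >= k]
    if len(usable) < 2:
        raise ValueError(
            "need >= 2 background regions with at least one k-mer window"
        )
    x = _proportions(count_kmers(cluster_seqs, k), kmers)
    per_region = np.vstack(
        [_proportions(count_kmers([s], k), kmers) for s in usable]
    )
    mu = per_region.mean(axis=0)
    if sigma_mode == "regions":
        sigma = per_region.std(axis=0, ddof=ddof)
    elif sigma_mode == "binomial":
        n_windows = sum(len(s) - k + 1 for s in usable)
        sigma = np.sqrt(mu * (1.0 - mu) / n_windows)
    else:
        raise ValueError(f"unknown sigma_mode {sigma_mode!r}")
    stats: list[KmerStat] = []
    for i, m in enumerate(kmers):
        s = float(sigma[i])
        zero = s == 0.0
        if zero:
            # constant background proportion: the direction is certain when the
            # cluster proportion departs from it, undefined when it matches
            diff = float(x[i]) - float(mu[i])
            z = float("nan") if diff == 0 else math.copysign(math.inf, diff)
        else:
            z = (float(x[i]) - float(mu[i])) / s
        stats.append(
            KmerStat(
                kmer=m,
                x_cluster=float(x[i]),
                mu_bg=float(mu[i]),
                sigma_bg=s,
                z=z,
                sigma_zero=zero,
            )
        )
    classify_kmers(stats)
    stats.sort(key=lambda st: (math.isnan(st.z), -st.z if not math.isnan(st.z) else 0.0))
    return stats


def classify_kmers(stats: list[KmerStat]) -> list[KmerStat]:
    """AU-rich (>=3 A or >=3 T among 5 bases) and ATG-containing flags, in place."""
    for st in stats:
        st.au_rich = st.kmer.count("A") >= 3 or st.kmer.count("T") >= 3
        st.atg_containing = "ATG" in st.kmer
    return stats


def stats_to_frame(stats: Sequence[KmerStat]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "kmer": [s.kmer for s in stats],
            "x_cluster": [s.x_cluster for s in stats],
            "mu_bg": [s.mu_bg for s in stats],
            "sigma_bg": [s.sigma_bg for s in stats],
            "z": [s.z for s in stats],
            "au_rich": [s.au_rich for s in stats],
            "atg_containing": [s.atg_containing for s in stats],
        }
    )
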