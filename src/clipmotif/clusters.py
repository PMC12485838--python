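"""PAR-CLIP binding-site cluster calling with a Poisson background model.

The background per-base mismatch rate is estimated from non-T-to-C
mismatches library-wide; each candidate interval's observed T->C count is
tested against a Poisson expectation proportional to the reference-T bases
it covers.  Candidates pass a Benjamini-Hochberg FDR filter plus read-depth
and distinct-conversion-position (loc_T2C) thresholds, and are ranked by
total conversion count (count_T2C).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import AlignedRead, TranscriptAnnotation

logger = logging.getLogger(__name__)

# Under a uniform-substitution background, T->C carries 1/12 of all
# base-substitution mass; the non-T2C count therefore covers 11/12 of it.
_UNIFORM_SUBSTITUTION_CORRECTION = 12.0 / 11.0

REGION_PRECEDENCE = ("utr3", "cds", "utr5", "intron", "unannotated")


@dataclass
class BackgroundModel:
    """Library-wide per-base background mismatch probability."""

    n_non_t2c: int
    aligned_bases: int
    r_bg: float


@dataclass
class Cluster:
    """A contiguous binding-site interval with its conversion statistics."""

    reference_name: str
    start: int
    end: int  # 0-based half-open
    read_count: int
    count_T2C: int
    loc_T2C: int
    covered_T_bases: int
    expected_T2C: float = float("nan")
    p_value: float = float("nan")
    q_value: float = float("nan")
    region: str = "unannotated"
    gene_id: str = ""

    @property
    def length(self) -> int:
        return self.end - self.start


def estimate_background(reads: Sequence[AlignedRead]) -> BackgroundModel:
    """r_bg = (non-T2C mismatches / aligned bases) x 12/11.

    The correction restores the T->C share excluded from the numerator,
    assuming substitutions are uniform over the 12 ordered base pairs.
    """
    aligned = sum(r.aligned_length for r in reads)
    if aligned == 0:
        raise ValueError("cannot estimate background from zero aligned bases")
    n_non = sum(
        1 for r in reads for m in r.mismatches if not m.is_t2c
    )
    return BackgroundModel(
        n_non_t2c=n_non,
        aligned_bases=aligned,
        r_bg=(n_non / aligned) * _UNIFORM_SUBSTITUTION_CORRECTION,
    )


def poisson_tail(k: int, mu: float) -> float:
    """Upper tail P(X >= k) for X ~ Poisson(mu), including k.

    k=0 returns 1 for any mu; mu=0 returns 0 for k>=1 (degenerate mass at 0).
    """
    if k < 0 or mu < 0:
        raise ValueError("k and mu must be non-negative")
    if k == 0:
        return 1.0
    return float(stats.poisson.sf(k - 1, mu))


def build_candidates(
    reads: Sequence[AlignedRead],
    reference: dict[str, str],
    min_depth: int = 3,
) -> list[Cluster]:
    """Maximal coverage>=1 intervals (read unions), filtered by read depth.

    Statistics are computed against the reference sequence: covered_T_bases
    sums, over reads in the candidate, the reference-T positions each read
    covers; count_T2C / loc_T2C tally T->C mismatch events and their distinct
    positions.
    """
    by_ref: dict[str, list[AlignedRead]] = {}
    for r in reads:
        if r.reference_name not in reference:
            raise ValueError(f"no reference sequence for {r.reference_name}")
        by_ref.setdefault(r.reference_name, []).append(r)
    out: list[Cluster] = []
    for ref_name in sorted(by_ref):
        group = sorted(by_ref[ref_name], key=lambda r: (r.start, r.end))
        seq = reference[ref_name]
        block: list[AlignedRead] = []
        block_end = -1
        for r in group:
            if block and r.start > block_end:  # touching reads stay contiguous
                c = _score_block(ref_name, block, block_end, seq)
                if c.read_count >= min_depth:
                    out.append(c)
                block = []
            block.append(r)
            block_end = max(block_end, r.end)
        if block:
            c = _score_block(ref_name, block, block_end, seq)
            if c.read_count >= min_depth:
                out.append(c)
    return out


def _score_block(
    ref_name: str, block: list[AlignedRead], block_end: int, seq: str
) -> Cluster:
    start = block[0].start
    covered_t = 0
    count_t2c = 0
    loc: set[int] = set()
    for r in block:
        covered_t += seq.count("T", r.start, r.end)
        for m in r.mismatches:
            if m.is_t2c:
                count_t2c += 1
                loc.add(m.reference_pos)
    return Cluster(
        reference_name=ref_name,
        start=start,
        end=block_end,
        read_count=len(block),
        count_T2C=count_t2c,
        loc_T2C=len(loc),
        covered_T_bases=covered_t,
    )


def annotate_cluster(
    cluster: Cluster, annotation: TranscriptAnnotation
) -> tuple[str, str]:
    """Majority-overlap region label; ties break utr3 > cds > utr5 > intron."""
    overlaps: dict[str, int] = {}
    for region, lo, hi in annotation.regions.get(cluster.reference_name, []):
        ov = min(cluster.end, hi) - max(cluster.start, lo)
        if ov > 0:
            overlaps[region] = overlaps.get(region, 0) + ov
    covered = sum(overlaps.values())
    if covered == 0:
        return "unannotated", ""
    if cluster.length - covered > 0:
        overlaps["unannotated"] = cluster.length - covered
    best = max(
        overlaps.items(),
        key=lambda kv: (kv[1], -REGION_PRECEDENCE.index(kv[0])),
    )[0]
    return best, annotation.gene_of.get(cluster.reference_name, "")


def call_clusters(
    reads: Sequence[AlignedRead],
    reference: dict[str, str],
    annotation: TranscriptAnnotation | None = None,
    min_depth: int = 3,
    min_loc_t2c: int = 2,
    alpha: float = 0.05,
) -> tuple[list[Cluster], BackgroundModel]:
    """Score, FDR-filter, annotate and rank candidate clusters.

    p = P(Poisson(r_bg * covered_T_bases) >= count_T2C); q-values are
    Benjamini-Hochberg over all candidates; retained clusters satisfy
    q <= alpha, read_count >= min_depth and loc_T2C >= min_loc_t2c, sorted by
    count_T2C descending.
    """
    bg = estimate_background(reads)
    candidates = build_candidates(reads, reference, min_depth=min_depth)
    if not candidates:
        logger.info("no candidate clusters at min_depth=%d", min_depth)
        return [], bg
    for c in candidates:
        c.expected_T2C = bg.r_bg * c.covered_T_bases
        c.p_value = poisson_tail(c.count_T2C, c.expected_T2C)
    qvals = multipletests([c.p_value for c in candidates], method="fdr_bh")[1]
    for c, q in zip(candidates, qvals):
        c.q_value = float(q)
        if annotation is not None:
            c.region, c.gene_id = annotate_cluster(c, annotation)
    kept = [
        c
        for c in candidates
        if c.q_value <= alpha and c.loc_T2C >= min_loc_t2c
    ]
    kept.sort(key=lambda c: (-c.count_T2C, -c.loc_T2C, c.reference_name, c.start))
    logger.info(
        "r_bg=%.4g; %d candidates, %d retained", bg.r_bg, len(candidates), len(kept)
    )
    return kept, bg


def score_candidates(
    reads: Sequence[AlignedRead],
    reference: dict[str, str],
    min_depth: int = 3,
) -> tuple[list[Cluster], BackgroundModel]:
    """All candidates with p/q values attached, unfiltered (for null diagnostics)."""
    bg = estimate_background(reads)
    candidates = build_candidates(reads, reference, min_depth=min_depth)
    for c in candidates:
        c.expected_T2C = bg.r_bg * c.covered_T_bases
        c.p_value = poisson_tail(c.count_T2C, c.expected_T2C)
    if candidates:
        qvals = multipletests([c.p_value for c in candidates], method="fdr_bh")[1]
        for c, q in zip(candidates, qvals):
            c.q_value = float(q)
    return candidates, bg


def select_top_clusters(
    clusters: Sequence[Cluster], n: int = 2000, min_reads: int = 10
) -> list[Cluster]:
    """Top-n clusters with >= min_reads reads, ranked by count_T2C.

    Ties break by loc_T2C descending then start ascending.
    """
    eligible = [c for c in clusters if c.read_count >= min_reads]
    eligible.sort(key=lambda c: (-c.count_T2C, -c.loc_T2C, c.start))
    return eligible[:n]
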