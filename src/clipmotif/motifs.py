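"""Scanning for the canonical heptamer and its single-nucleotide variants.

The canonical element is ``ATGAATT`` (DNA alphabet; U -> T).  Variant
enumeration produces the 21 single-substitution 7-mers; scanning is exact,
overlap-permitting, and restricted to region bounds.  Gene summaries count
canonical hits per region and within called cluster intervals, plus
per-variant presence in the 3'UTR under an exclusivity rule: a gene counts
for a variant only if its 3'UTR carries that variant and no canonical copy,
isolating the variant's own effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .clusters import Cluster
from .io_formats import TranscriptAnnotation
from .simulate import CANONICAL_MOTIF

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class VariantSpec:
    """A 7-mer to scan for: canonical, a single substitution, or custom."""

    label: str
    seq: str
    kind: str  # "canonical" | "single_sub" | "custom"
    position: int | None = None  # 1-based motif position for single_sub
    base: str | None = None


@dataclass(frozen=True)
class MotifHit:
    transcript_id: str
    region: str
    start: int  # 0-based transcript offset
    variant_label: str

    @property
    def end(self) -> int:
        return self.start + 7


@dataclass
class GeneMotifSummary:
    gene_id: str
    transcript_id: str
    n_utr5: int = 0
    n_cds: int = 0
    n_utr3: int = 0
    n_in_clusters: int = 0
    variant_presence: dict[str, bool] = field(default_factory=dict)

    @property
    def n_total(self) -> int:
        return self.n_utr5 + self.n_cds + self.n_utr3


def canonical_spec(motif: str = CANONICAL_MOTIF) -> VariantSpec:
    return VariantSpec(label="canonical", seq=motif, kind="canonical")


def enumerate_variants(motif: str = CANONICAL_MOTIF) -> list[VariantSpec]:
    """All 3 x len(motif) single-substitution variants, canonical excluded."""
    if set(motif) - set("ACGT"):
        raise ValueError(f"motif {motif!r} is not over ACGT")
    out = []
    for i, ref in enumerate(motif):
        for alt in "ACGT":
            if alt == ref:
                continue
            out.append(
                VariantSpec(
                    label=f"pos{i + 1}{alt}",
                    seq=motif[:i] + alt + motif[i + 1:],
                    kind="single_sub",
                    position=i + 1,
                    base=alt,
                )
            )
    return out


def scan(
    sequence: str,
    spec: VariantSpec,
    bounds: tuple[int, int] | None = None,
    transcript_id: str = "",
    region: str = "",
) -> list[MotifHit]:
    """Exact overlapping occurrences with the full window inside bounds."""
    lo, hi = bounds if bounds is not None else (0, len(sequence))
    if lo < 0 or hi > len(sequence):
        raise ValueError("region bounds outside sequence")
    k = len(spec.seq)
    hits = []
    pos = sequence.find(spec.seq, lo)
    while pos != -1 and pos + k <= hi:
        hits.append(
            MotifHit(
                transcript_id=transcript_id,
                region=region,
                start=pos,
                variant_label=spec.label,
            )
        )
        pos = sequence.find(spec.seq, pos + 1)
    return hits


def scan_transcripts(
    reference: Mapping[str, str],
    annotation: TranscriptAnnotation,
    specs: Sequence[VariantSpec],
) -> list[MotifHit]:
    """Scan every annotated region of every transcript for each spec."""
    hits: list[MotifHit] = []
    for tid, regions in annotation.regions.items():
        seq = reference.get(tid)
        if seq is None:
            continue
        for region, lo, hi in regions:
            for spec in specs:
                hits.extend(
                    scan(seq, spec, (lo, hi), transcript_id=tid, region=region)
                )
    hits.sort(key=lambda h: (h.transcript_id, h.start, h.variant_label))
    return hits


def _representative_transcripts(
    annotation: TranscriptAnnotation,
) -> dict[str, str]:
    """gene -> transcript with the longest annotated 3'UTR."""
    best: dict[str, tuple[int, str]] = {}
    multi = set()
    for tid in annotation.regions:
        gene = annotation.gene_of.get(tid, tid)
        b = annotation.region_bounds(tid, "utr3")
        u3 = (b[1] - b[0]) if b else 0
        if gene in best:
            multi.add(gene)
        if gene not in best or (u3, tid) > best[gene]:
            best[gene] = (u3, tid)
    if multi:
        logger.info(
            "%d genes have multiple transcripts; using longest-3'UTR representative",
            len(multi),
        )
    return {g: tid for g, (_, tid) in best.items()}


def summarize_genes(
    hits: Sequence[MotifHit],
    annotation: TranscriptAnnotation,
    clusters: Sequence[Cluster] = (),
    exclusive: bool = True,
) -> dict[str, GeneMotifSummary]:
    """Per-gene canonical counts, in-cluster counts and 3'UTR variant flags.

    A hit counts as in-cluster only when its whole window lies within a
    cluster interval on the same transcript.  With ``exclusive`` (default) a
    variant flag requires zero canonical 3'UTR copies in the gene.
    """
    rep = _representative_transcripts(annotation)
    tid_to_gene = {tid: g for g, tid in rep.items()}
    cluster_ivals: dict[str, list[tuple[int, int]]] = {}
    for c in clusters:
        cluster_ivals.setdefault(c.reference_name, []).append((c.start, c.end))
    summaries: dict[str, GeneMotifSummary] = {
        g: GeneMotifSummary(gene_id=g, transcript_id=tid) for g, tid in rep.items()
    }
    variant_hits_utr3: dict[str, set[str]] = {}
    for h in hits:
        gene = tid_to_gene.get(h.transcript_id)
        if gene is None:
            continue
        s = summaries[gene]
        if h.variant_label == "canonical":
            if h.region == "utr5":
                s.n_utr5 += 1
            elif h.region == "cds":
                s.n_cds += 1
            elif h.region == "utr3":
                s.n_utr3 += 1
            if any(
                lo <= h.start and h.end <= hi
                for lo, hi in cluster_ivals.get(h.transcript_id, [])
            ):
                s.n_in_clusters += 1
        elif h.region == "utr3":
            variant_hits_utr3.setdefault(gene, set()).add(h.variant_label)
    labels = sorted({h.variant_label for h in hits if h.variant_label != "canonical"})
    for g, s in summaries.items():
        present = variant_hits_utr3.get(g, set())
        for lab in labels:
            ok = lab in present
            if exclusive and s.n_utr3 > 0:
                ok = False
            s.variant_presence[lab] = ok
    return summaries


def summaries_to_frame(summaries: Mapping[str, GeneMotifSummary]) -> pd.DataFrame:
    rows = []
    for g, s in summaries.items():
        row = {
            "gene_id": g,
            "transcript_id": s.transcript_id,
            "n_utr5": s.n_utr5,
            "n_cds": s.n_cds,
            "n_utr3": s.n_utr3,
            "n_in_clusters": s.n_in_clusters,
        }
        for lab, flag in s.variant_presence.items():
            row[f"variant_{lab}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)
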