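"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; 1-based inclusive
GTF coordinates are converted at the file boundary only.  SAM I/O goes
through pysam; FASTA through Biopython; GTF reading through gffutils.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import GTF_FEATURE, SimulatedRead, TranscriptModel

logger = logging.getLogger(__name__)

_FEATURE_TO_REGION = {v: k for k, v in GTF_FEATURE.items()}
_FEATURE_TO_REGION["UTR5"] = "utr5"
_FEATURE_TO_REGION["UTR3"] = "utr3"

CLUSTER_COLUMNS = [
    "reference_name",
    "start",
    "end",
    "name",
    "score",
    "strand",
    "read_count",
    "count_T2C",
    "loc_T2C",
    "covered_T_bases",
    "expected_T2C",
    "p_value",
    "q_value",
    "region",
    "gene_id",
]


@dataclass(frozen=True)
class MismatchEvent:
    """One read-vs-reference substitution."""

    reference_name: str
    reference_pos: int  # 0-based
    ref_base: str
    read_base: str
    read_id: str

    def __post_init__(self) -> None:
        if self.ref_base == self.read_base:
            raise ValueError("mismatch event with identical bases")

    @property
    def is_t2c(self) -> bool:
        return self.ref_base == "T" and self.read_base == "C"


@dataclass
class AlignedRead:
    """An ungapped primary alignment with its decoded mismatches."""

    read_id: str
    reference_name: str
    start: int
    end: int  # 0-based half-open
    mismatches: list[MismatchEvent] = field(default_factory=list)

    @property
    def aligned_length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA / GTF
# ---------------------------------------------------------------------------


def write_fasta(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(t.sequence), id=t.transcript_id, description="")
        for t in transcripts
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gtf(transcripts: Sequence[TranscriptModel], path: str | Path) -> None:
    """Transcript-space GTF: one line per non-empty region, 1-based inclusive."""
    with open(path, "w") as fh:
        for t in transcripts:
            for region in ("utr5", "cds", "utr3"):
                lo, hi = t.region_bounds(region)
                if hi <= lo:
                    continue
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
                )
                fh.write(
                    "\t".join(
                        [
                            t.transcript_id,
                            "clipmotif_sim",
                            GTF_FEATURE[region],
                            str(lo + 1),
                            str(hi),
                            ".",
                            "+",
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


@dataclass
class TranscriptAnnotation:
    """Ordered region intervals per transcript, 0-based half-open."""

    regions: dict[str, list[tuple[str, int, int]]]  # transcript -> (region, lo, hi)
    gene_of: dict[str, str]  # transcript -> gene

    def region_at(self, transcript_id: str, pos: int) -> str:
        for region, lo, hi in self.regions.get(transcript_id, []):
            if lo <= pos < hi:
                return region
        return "unannotated"

    def transcripts(self) -> list[str]:
        return list(self.regions)

    def region_bounds(self, transcript_id: str, region: str) -> tuple[int, int] | None:
        for r, lo, hi in self.regions.get(transcript_id, []):
            if r == region:
                return lo, hi
        return None


def read_annotation(gtf_path: str | Path) -> TranscriptAnnotation:
    """Load UTR/CDS features from a GTF into 0-based half-open intervals."""
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    regions: dict[str, list[tuple[str, int, int]]] = {}
    gene_of: dict[str, str] = {}
    for feat in db.all_features():
        region = _FEATURE_TO_REGION.get(feat.featuretype)
        if region is None:
            continue
        tid = feat.attributes.get("transcript_id", [feat.seqid])[0]
        gid = feat.attributes.get("gene_id", [""])[0]
        lo, hi = feat.start - 1, feat.end  # GTF 1-based inclusive -> half-open
        regions.setdefault(tid, []).append((region, lo, hi))
        if gid:
            gene_of[tid] = gid
    for tid, ivals in regions.items():
        ivals.sort(key=lambda r: r[1])
        for (_, _, hi_a), (_, lo_b, _) in zip(ivals, ivals[1:]):
            if lo_b < hi_a:
                raise ValueError(
                    f"overlapping region features for transcript {tid}"
                )
    return TranscriptAnnotation(regions=regions, gene_of=gene_of)


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------


def _md_and_nm(ref: str, read: str) -> tuple[str, int]:
    """MD tag and NM count for an ungapped alignment."""
    md = []
    run = 0
    nm = 0
    for r, q in zip(ref, read):
        if r == q:
            run += 1
        else:
            md.append(str(run))
            md.append(r)
            run = 0
            nm += 1
    md.append(str(run))
    return "".join(md), nm


def write_sam(
    reads: Sequence[SimulatedRead],
    transcripts: Sequence[TranscriptModel],
    path: str | Path,
) -> None:
    """Coordinate-sorted SAM with MD/NM tags consistent with the reference."""
    ref_seq = {t.transcript_id: t.sequence for t in transcripts}
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [
            {"SN": t.transcript_id, "LN": t.length} for t in transcripts
        ],
    }
    order = {t.transcript_id: i for i, t in enumerate(transcripts)}
    reads = sorted(reads, key=lambda r: (order[r.reference_name], r.start))
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            ref = ref_seq[r.reference_name][r.start: r.start + len(r.sequence)]
            md, nm = _md_and_nm(ref, r.sequence)
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.read_id
            a.query_sequence = r.sequence
            a.flag = 0
            a.reference_id = order[r.reference_name]
            a.reference_start = r.start
            a.mapping_quality = 255
            a.cigartuples = [(0, len(r.sequence))]
            a.set_tag("MD", md)
            a.set_tag("NM", nm)
            out.write(a)


def read_alignments(
    sam_path: str | Path, max_mismatches: int | None = 2
) -> list[AlignedRead]:
    """Decode ungapped primary alignments and their mismatch events.

    Reads with indels or reference skips are skipped with a counted warning;
    a record lacking an MD tag is an error.  ``max_mismatches`` drops reads
    with more substitutions (mirroring a strict end-to-end alignment); pass
    None to disable.
    """
    out: list[AlignedRead] = []
    n_skipped_indel = 0
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=True) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if any(op not in (0, 7, 8) for op, _ in rec.cigartuples or []):
                n_skipped_indel += 1
                continue
            if not rec.has_tag("MD"):
                raise ValueError(f"record {rec.query_name} has no MD tag")
            mismatches = []
            for qpos, rpos, ref_base in rec.get_aligned_pairs(with_seq=True):
                if qpos is None or rpos is None or ref_base is None:
                    continue
                if ref_base.islower():
                    mismatches.append(
                        MismatchEvent(
                            reference_name=rec.reference_name,
                            reference_pos=rpos,
                            ref_base=ref_base.upper(),
                            read_base=rec.query_sequence[qpos].upper(),
                            read_id=rec.query_name,
                        )
                    )
            if max_mismatches is not None and len(mismatches) > max_mismatches:
                continue
            out.append(
                AlignedRead(
                    read_id=rec.query_name,
                    reference_name=rec.reference_name,
                    start=rec.reference_start,
                    end=rec.reference_end,
                    mismatches=mismatches,
                )
            )
    if n_skipped_indel:
        logger.warning("skipped %d indel-containing reads", n_skipped_indel)
    return out


# ---------------------------------------------------------------------------
# Cluster BED6+
# ---------------------------------------------------------------------------


def write_clusters(clusters: Sequence, path: str | Path) -> None:
    """BED6+ with one documented header line; coordinates 0-based half-open."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(CLUSTER_COLUMNS) + "\n")
        for i, c in enumerate(clusters):
            fh.write(
                "\t".join(
                    [
                        c.reference_name,
                        str(c.start),
                        str(c.end),
                        f"cluster{i + 1}",
                        str(c.count_T2C),
                        "+",
                        str(c.read_count),
                        str(c.count_T2C),
                        str(c.loc_T2C),
                        str(c.covered_T_bases),
                        f"{c.expected_T2C:.6g}",
                        f"{c.p_value:.6g}",
                        f"{c.q_value:.6g}",
                        c.region,
                        c.gene_id,
                    ]
                )
                + "\n"
            )


def read_clusters(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", names=CLUSTER_COLUMNS, skiprows=1)
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=CLUSTER_COLUMNS)
    return df
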