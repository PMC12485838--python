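"""Synthetic PAR-CLIP and RNA-seq data with known ground truth.

Generates transcript-space data with the statistical structure the
downstream analyses assume:

* transcriptomes whose scanned regions are free of the canonical heptamer
  ``ATGAATT`` and all of its 21 single-nucleotide variants, except where
  motifs are explicitly planted;
* PAR-CLIP read pileups around planted binding sites, where crosslinking
  converts reference T to read C at rate ``p_conv`` on top of a uniform
  per-base background mismatch rate ``p_bg``;
* negative-binomial count matrices in which induced-condition means are
  suppressed 2**(-delta) per canonical 3'UTR motif copy.

RNA motifs are represented in DNA alphabet (U -> T) throughout, matching
every file format the pipeline touches.  Coordinates are 0-based half-open
on the transcript; conversion to 1-based GTF happens only on write.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

CANONICAL_MOTIF = "ATGAATT"
REGIONS = ("utr5", "cds", "utr3")
_BASES = np.frombuffer(b"ACGT", dtype="S1")
_ALT_BASES = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}

# GTF feature names used on write (Ensembl vocabulary).
GTF_FEATURE = {"utr5": "five_prime_utr", "cds": "CDS", "utr3": "three_prime_utr"}


def motif_neighborhood(motif: str = CANONICAL_MOTIF) -> frozenset[str]:
    """The motif plus all single-substitution variants (22 strings for a 7-mer)."""
    out = {motif}
    for i, ref in enumerate(motif):
        for alt in _ALT_BASES[ref]:
            out.add(motif[:i] + alt + motif[i + 1:])
    return frozenset(out)


_FORBIDDEN = motif_neighborhood()


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: id, gene, region lengths and its full sequence."""

    transcript_id: str
    gene_id: str
    utr5_len: int
    cds_len: int
    utr3_len: int
    sequence: str

    def __post_init__(self) -> None:
        if self.utr5_len + self.cds_len + self.utr3_len != len(self.sequence):
            raise ValueError(
                f"{self.transcript_id}: region lengths do not sum to sequence length"
            )
        if min(self.utr5_len, self.cds_len, self.utr3_len) < 0:
            raise ValueError(f"{self.transcript_id}: negative region length")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def region_bounds(self, region: str) -> tuple[int, int]:
        """0-based half-open bounds of a region on the transcript."""
        if region == "utr5":
            return 0, self.utr5_len
        if region == "cds":
            return self.utr5_len, self.utr5_len + self.cds_len
        if region == "utr3":
            return self.utr5_len + self.cds_len, self.length
        raise ValueError(f"unknown region {region!r}")


@dataclass(frozen=True)
class MotifPlacement:
    """A motif copy planted at a transcript offset inside one region."""

    transcript_id: str
    region: str
    start: int
    motif_seq: str

    @property
    def end(self) -> int:
        return self.start + len(self.motif_seq)


@dataclass
class SimConfig:
    """All knobs of the generator; identical configs reproduce outputs exactly.

    delta is the per-canonical-motif suppression in log2 units applied to the
    induced condition mean; p_conv the T->C conversion probability at a
    crosslinked T; p_bg the per-base background mismatch probability.
    """

    seed: int = 0
    n_transcripts: int = 300
    utr5_range: tuple[int, int] = (50, 150)
    cds_range: tuple[int, int] = (300, 900)
    utr3_range: tuple[int, int] = (200, 600)
    expression_mu: float = 6.0
    expression_sigma: float = 1.0
    nb_dispersion: float = 0.05
    n_replicates: int = 4
    delta: float = 1.0
    read_depth: int = 50
    bg_read_rate: float = 2.0
    p_conv: float = 0.3
    p_bg: float = 0.002
    read_len: int = 30
    max_rejection_attempts: int = 1000

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_conv <= 1.0):
            raise ValueError("p_conv must be in [0, 1]")
        if not (0.0 <= self.p_bg <= 1.0):
            raise ValueError("p_bg must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        for name in ("utr5_range", "cds_range", "utr3_range"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"{name} must satisfy 0 <= lo <= hi")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


# ---------------------------------------------------------------------------
# Transcriptome generation
# ---------------------------------------------------------------------------


def _random_clean_region(rng: np.random.Generator, length: int, max_attempts: int) -> str:
    """A random sequence of `length` containing none of the forbidden 7-mers."""
    for _ in range(max_attempts):
        seq = rng.choice(_BASES, size=length).tobytes().decode()
        if not _contains_forbidden(seq):
            return seq
    raise RuntimeError(
        f"could not sample a motif-free region of length {length} in "
        f"{max_attempts} attempts"
    )


def _contains_forbidden(seq: str) -> bool:
    k = len(CANONICAL_MOTIF)
    return any(seq[i: i + k] in _FORBIDDEN for i in range(len(seq) - k + 1))


def generate_transcriptome(config: SimConfig) -> list[TranscriptModel]:
    """Sample transcripts with motif-free 5'UTR/CDS/3'UTR sequence.

    Deterministic for a given config.  Region sequences are rejection-sampled
    so that no canonical-motif neighbour occurs anywhere except where
    :func:`plant_motifs` later writes one.  Junction-spanning occurrences are
    removed by resampling the downstream region.
    """
    rng = np.random.default_rng(config.seed)
    transcripts: list[TranscriptModel] = []
    for i in range(config.n_transcripts):
        u5 = int(rng.integers(config.utr5_range[0], config.utr5_range[1] + 1))
        cds = int(rng.integers(config.cds_range[0], config.cds_range[1] + 1))
        u3 = int(rng.integers(config.utr3_range[0], config.utr3_range[1] + 1))
        for _ in range(config.max_rejection_attempts):
            parts = [
                _random_clean_region(rng, n, config.max_rejection_attempts)
                for n in (u5, cds, u3)
            ]
            seq = "".join(parts)
            if not _contains_forbidden(seq):  # junction check
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not assemble a motif-free transcript")
        transcripts.append(
            TranscriptModel(
                transcript_id=f"tx{i:04d}",
                gene_id=f"gene{i:04d}",
                utr5_len=u5,
                cds_len=cds,
                utr3_len=u3,
                sequence=seq,
            )
        )
    return transcripts


# ---------------------------------------------------------------------------
# Motif planting
# ---------------------------------------------------------------------------


def plant_motifs(
    transcripts: list[TranscriptModel],
    plan: Sequence[tuple[str, str, str, int]],
    seed: int = 0,
    max_attempts: int = 1000,
) -> tuple[list[TranscriptModel], list[MotifPlacement]]:
    """Overwrite transcript sequence with planted motif copies.

    ``plan`` rows are ``(transcript_id, region, motif_seq, n_copies)``.
    Placements never overlap; offsets are redrawn until the rescan of the
    edited region finds exactly the planted occurrences of the canonical
    neighbourhood (overwriting can otherwise create chance variants at the
    seams).  Returns new transcript objects and the placement list.
    """
    rng = np.random.default_rng(seed)
    by_id = {t.transcript_id: t for t in transcripts}
    placements: list[MotifPlacement] = []
    for transcript_id, region, motif_seq, n_copies in plan:
        if n_copies == 0:
            continue
        motif_seq = motif_seq.upper()
        if set(motif_seq) - set("ACGT"):
            raise ValueError(f"motif {motif_seq!r} is not over ACGT")
        t = by_id[transcript_id]
        lo, hi = t.region_bounds(region)
        k = len(motif_seq)
        if hi - lo < k * n_copies:
            raise ValueError(
                f"{transcript_id}:{region} ({hi - lo} nt) cannot hold "
                f"{n_copies} non-overlapping copies of a {k}-mer"
            )
        for _ in range(max_attempts):
            starts = _draw_nonoverlapping(rng, lo, hi, k, n_copies)
            seq = t.sequence
            for s in starts:
                seq = seq[:s] + motif_seq + seq[s + k:]
            found = _scan_neighborhood(seq, lo, hi)
            wanted = {(s, motif_seq) for s in starts}
            prior = {
                (p.start, p.motif_seq) for p in placements
                if p.transcript_id == transcript_id and p.region == region
            }
            if found == wanted | prior:
                t = dataclasses.replace(t, sequence=seq)
                by_id[transcript_id] = t
                placements.extend(
                    MotifPlacement(transcript_id, region, s, motif_seq)
                    for s in sorted(starts)
                )
                break
        else:
            raise RuntimeError(
                f"could not plant {n_copies}x {motif_seq} in "
                f"{transcript_id}:{region} without spurious neighbours"
            )
    out = [by_id[t.transcript_id] for t in transcripts]
    placements.sort(key=lambda p: (p.transcript_id, p.start))
    return out, placements


def _draw_nonoverlapping(
    rng: np.random.Generator, lo: int, hi: int, k: int, n: int
) -> list[int]:
    for _ in range(1000):
        starts = sorted(int(rng.integers(lo, hi - k + 1)) for _ in range(n))
        if all(b - a >= k for a, b in zip(starts, starts[1:])):
            return starts
    raise RuntimeError("could not draw non-overlapping placements")


def _scan_neighborhood(seq: str, lo: int, hi: int) -> set[tuple[int, str]]:
    k = len(CANONICAL_MOTIF)
    return {
        (i, seq[i: i + k])
        for i in range(lo, hi - k + 1)
        if seq[i: i + k] in _FORBIDDEN
    }


# ---------------------------------------------------------------------------
# PAR-CLIP read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedRead:
    """A simulated ungapped alignment in transcript space."""

    read_id: str
    reference_name: str
    start: int  # 0-based
    sequence: str
    n_conversions: int  # planted T->C events (truth, not counting background)


@dataclass
class ParclipSim:
    """Simulated PAR-CLIP library plus its ground truth."""

    reads: list[SimulatedRead]
    n_conversions_total: int
    truth: pd.DataFrame  # one row per placement: transcript_id, start, end, n_reads


def simulate_parclip(
    transcripts: list[TranscriptModel],
    placements: Sequence[MotifPlacement],
    config: SimConfig,
) -> ParclipSim:
    """Draw reads around placements plus uniform background reads.

    Signal reads start uniformly over the window in which the read fully
    covers its placement (clipped at transcript bounds).  Each reference T
    inside the placement converts to C with ``p_conv``; every other aligned
    base mismatches with ``p_bg`` to a uniform alternative.  Background read
    counts per transcript are Poisson(``bg_read_rate``).
    """
    by_id = {t.transcript_id: t for t in transcripts}
    shortest = min((t.length for t in transcripts), default=0)
    if transcripts and config.read_len > shortest:
        raise ValueError(
            f"read_len {config.read_len} exceeds shortest transcript ({shortest} nt)"
        )
    rng = np.random.default_rng(config.seed + 1)
    reads: list[SimulatedRead] = []
    truth_rows = []
    n_conv_total = 0
    serial = 0
    for p in placements:
        t = by_id[p.transcript_id]
        lo = max(0, p.end - config.read_len)
        hi = min(t.length - config.read_len, p.start)
        if hi < lo:  # read cannot fully cover the placement; center instead
            lo = hi = max(0, min(t.length - config.read_len, p.start - (config.read_len - len(p.motif_seq)) // 2))
        n_reads = 0
        for _ in range(config.read_depth):
            start = int(rng.integers(lo, hi + 1))
            read, n_conv = _make_read(rng, t, start, config, placement=p)
            read.read_id = f"read{serial:07d}"
            serial += 1
            reads.append(read)
            n_conv_total += n_conv
            n_reads += 1
        truth_rows.append(
            {
                "transcript_id": p.transcript_id,
                "region": p.region,
                "start": p.start,
                "end": p.end,
                "motif_seq": p.motif_seq,
                "n_reads": n_reads,
            }
        )
    for t in transcripts:
        for _ in range(int(rng.poisson(config.bg_read_rate))):
            start = int(rng.integers(0, t.length - config.read_len + 1))
            read, n_conv = _make_read(rng, t, start, config, placement=None)
            read.read_id = f"read{serial:07d}"
            serial += 1
            reads.append(read)
            n_conv_total += n_conv
    order = {t.transcript_id: i for i, t in enumerate(transcripts)}
    reads.sort(key=lambda r: (order[r.reference_name], r.start))
    truth = pd.DataFrame(
        truth_rows,
        columns=["transcript_id", "region", "start", "end", "motif_seq", "n_reads"],
    )
    return ParclipSim(reads=reads, n_conversions_total=n_conv_total, truth=truth)


def _make_read(
    rng: np.random.Generator,
    t: TranscriptModel,
    start: int,
    config: SimConfig,
    placement: MotifPlacement | None,
) -> tuple[SimulatedRead, int]:
    end = start + config.read_len
    ref = t.sequence[start:end]
    bases = list(ref)
    n_conv = 0
    converted = set()
    if placement is not None and config.p_conv > 0:
        for i, b in enumerate(bases):
            pos = start + i
            if placement.start <= pos < placement.end and b == "T":
                if rng.random() < config.p_conv:
                    bases[i] = "C"
                    converted.add(i)
                    n_conv += 1
    if config.p_bg > 0:
        hits = np.flatnonzero(rng.random(len(bases)) < config.p_bg)
        for i in hits:
            if i in converted:
                continue
            alts = _ALT_BASES[ref[i]]
            bases[i] = alts[int(rng.integers(3))]
    read = SimulatedRead(
        read_id="",
        reference_name=t.transcript_id,
        start=start,
        sequence="".join(bases),
        n_conversions=n_conv,
    )
    return read, n_conv


# ---------------------------------------------------------------------------
# Count-matrix simulation
# ---------------------------------------------------------------------------


@dataclass
class CountSim:
    """Simulated two-condition count matrix plus per-gene truth."""

    counts: pd.DataFrame  # genes x samples
    design: pd.DataFrame  # sample, condition
    truth: pd.DataFrame  # gene_id, k_canonical, true_delta_total, mu_control


def simulate_counts(
    transcripts: list[TranscriptModel],
    placements: Sequence[MotifPlacement],
    config: SimConfig,
    variant_delta: dict[str, float] | None = None,
) -> CountSim:
    """Negative-binomial counts for control vs induced conditions.

    Control means are log-normal; the induced mean of gene g is
    ``mu_g * 2**(-delta * k_g)`` where ``k_g`` counts canonical placements in
    g's 3'UTR.  Non-canonical placements contribute nothing unless
    ``variant_delta`` maps their sequence to a per-copy effect.
    """
    if config.n_replicates < 2:
        raise ValueError("need >= 2 replicates per condition")
    rng = np.random.default_rng(config.seed + 2)
    genes = [t.gene_id for t in transcripts]
    tx_gene = {t.transcript_id: t.gene_id for t in transcripts}
    k_canon = {g: 0 for g in genes}
    delta_total = {g: 0.0 for g in genes}
    for p in placements:
        if p.region != "utr3":
            continue
        g = tx_gene[p.transcript_id]
        if p.motif_seq == CANONICAL_MOTIF:
            k_canon[g] += 1
            delta_total[g] += config.delta
        elif variant_delta and p.motif_seq in variant_delta:
            delta_total[g] += variant_delta[p.motif_seq]
    mu_ctl = rng.lognormal(config.expression_mu, config.expression_sigma, len(genes))
    mu_ind = mu_ctl * np.exp2(-np.array([delta_total[g] for g in genes]))
    n_rep = config.n_replicates
    size = 1.0 / config.nb_dispersion  # NB "number of successes" parameter

    def draw(mu: np.ndarray) -> np.ndarray:
        p = size / (size + mu[:, None])
        return rng.negative_binomial(size, p, (len(mu), n_rep))

    ctl = draw(mu_ctl)
    ind = draw(mu_ind)
    samples = [f"ctl_{i + 1}" for i in range(n_rep)] + [f"ind_{i + 1}" for i in range(n_rep)]
    counts = pd.DataFrame(
        np.hstack([ctl, ind]), index=pd.Index(genes, name="gene_id"), columns=samples
    )
    design = pd.DataFrame(
        {"sample": samples, "condition": ["control"] * n_rep + ["induced"] * n_rep}
    )
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "k_canonical": [k_canon[g] for g in genes],
            "true_delta_total": [delta_total[g] for g in genes],
            "mu_control": mu_ctl,
        }
    )
    return CountSim(counts=counts, design=design, truth=truth)
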