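"""Shared fixtures: a small planted simulation written to disk once per session."""

from __future__ import annotations

import pytest

import clipmotif as cm

PLANTED_EVERY = 3  # every third transcript gets one canonical 3'UTR motif


@pytest.fixture(scope="session")
def small_config() -> cm.SimConfig:
    return cm.SimConfig(n_transcripts=60, seed=11)


@pytest.fixture(scope="session")
def planted_world(small_config):
    """Transcriptome with one canonical 3'UTR motif in every third transcript."""
    tx = cm.generate_transcriptome(small_config)
    plan = [
        (f"tx{i:04d}", "utr3", cm.CANONICAL_MOTIF, 1)
        for i in range(0, small_config.n_transcripts, PLANTED_EVERY)
    ]
    tx, placements = cm.plant_motifs(tx, plan, seed=small_config.seed)
    return tx, placements


@pytest.fixture(scope="session")
def sim_files(planted_world, small_config, tmp_path_factory):
    """FASTA/GTF/SAM on disk plus the in-memory simulation truth."""
    tx, placements = planted_world
    sim = cm.simulate_parclip(tx, placements, small_config)
    d = tmp_path_factory.mktemp("sim")
    cm.write_fasta(tx, d / "transcripts.fa")
    cm.write_gtf(tx, d / "transcripts.gtf")
    cm.write_sam(sim.reads, tx, d / "parclip.sam")
    return {
        "dir": d,
        "fasta": d / "transcripts.fa",
        "gtf": d / "transcripts.gtf",
        "sam": d / "parclip.sam",
        "transcripts": tx,
        "placements": placements,
        "sim": sim,
    }


@pytest.fixture(scope="session")
def called(sim_files):
    """Reads, reference, annotation and called clusters for the small world."""
    reads = cm.read_alignments(sim_files["sam"])
    reference = cm.read_fasta(sim_files["fasta"])
    annotation = cm.read_annotation(sim_files["gtf"])
    clusters, bg = cm.call_clusters(reads, reference, annotation)
    return {
        "reads": reads,
        "reference": reference,
        "annotation": annotation,
        "clusters": clusters,
        "background": bg,
    }
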