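"""Shared fixtures: a small simulated study and tiny hand-built inputs."""

from __future__ import annotations

import numpy as np
import pytest

from m5cpipe.simulate import (
    SimConfig,
    simulate_methylome,
    simulate_pileups,
    simulate_transcriptome,
)
from m5cpipe.transcripts import TranscriptModel


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated study: 50 transcripts, 40 true sites, 2 replicates."""
    cfg = SimConfig(seed=11, n_transcripts=50, n_true_sites=40)
    genome, models = simulate_transcriptome(cfg)
    genome, truth = simulate_methylome(genome, models, cfg)
    pileups = simulate_pileups(genome, truth, cfg)
    return {"config": cfg, "genome": genome, "models": models,
            "truth": truth, "pileups": pileups}


@pytest.fixture
def toy_transcript():
    """Two-exon coding transcript on the plus strand.

    Exons (100, 160) + (200, 260): 120 nt mature length; CDS covers
    transcript offsets 30..90 (60 nt, divisible by 3).
    """
    return TranscriptModel(
        "T1", "G1", "chr1", "+", [(100, 160), (200, 260)],
        cds_start=30, cds_end=90,
    )


def write_sam(path, reads, contigs):
    """Write a minimal SAM file.

    ``reads`` are dicts with name, flag, chrom, pos (0-based), mapq, cigar,
    seq, qual.  ``contigs`` maps name -> length.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for name, length in contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{length}\n")
        for r in sorted(reads, key=lambda r: (r["chrom"], r["pos"])):
            fh.write(
                f"{r['name']}\t{r['flag']}\t{r['chrom']}\t{r['pos'] + 1}\t"
                f"{r.get('mapq', 60)}\t{r['cigar']}\t*\t0\t0\t"
                f"{r['seq']}\t{r['qual']}\n"
            )
    return path


@pytest.fixture
def sam_writer():
    return write_sam
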