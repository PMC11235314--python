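"""Transcript models and their coordinate arithmetic.

A :class:`TranscriptModel` stores the exon structure of one transcript
(genomic, 0-based half-open intervals) together with the CDS expressed in
*transcript* coordinates, so that mature-mRNA positions can be mapped to
5'UTR / CDS / 3'UTR regions without re-deriving splice structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = ["TranscriptModel", "read_bed12", "write_bed12"]


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Sequence[tuple[int, int]]  # genomic, sorted, half-open, disjoint
    cds_start: int | None = None      # transcript coordinates
    cds_end: int | None = None
    biotype: str = "protein_coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = [(int(s), int(e)) for s, e in self.exons]
        if not exons:
            raise ValueError("transcript must have at least one exon")
        for s, e in exons:
            if e <= s:
                raise ValueError(f"empty or inverted exon ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError("exon blocks must be sorted and disjoint")
        self.exons = exons
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError("cds_start and cds_end must be set together")
        if self.is_coding:
            if not (0 <= self.cds_start < self.cds_end <= self.length):
                raise ValueError("CDS outside transcript bounds")
            if (self.cds_end - self.cds_start) % 3 != 0:
                raise ValueError("CDS length must be divisible by 3")

    # ------------------------------------------------------------------
    @property
    def is_coding(self) -> bool:
        return self.cds_start is not None

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def utr5_length(self) -> int:
        return self.cds_start if self.is_coding else 0

    @property
    def cds_length(self) -> int:
        return (self.cds_end - self.cds_start) if self.is_coding else 0

    @property
    def utr3_length(self) -> int:
        return (self.length - self.cds_end) if self.is_coding else 0

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) of the whole transcript."""
        return self.exons[0][0], self.exons[-1][1]

    # ------------------------------------------------------------------
    def genomic_to_transcript(self, pos: int) -> int | None:
        """Map a genomic position to a mature-transcript offset.

        Returns ``None`` for intronic or out-of-span positions.  On the minus
        strand transcript coordinates run 3'->5' in genome space.
        """
        offset = 0
        hit = None
        for s, e in self.exons:
            if s <= pos < e:
                hit = offset + (pos - s)
                break
            offset += e - s
        if hit is None:
            return None
        return hit if self.strand == "+" else self.length - 1 - hit

    def transcript_to_genomic(self, tpos: int) -> int:
        if not 0 <= tpos < self.length:
            raise ValueError(f"transcript position {tpos} outside [0, {self.length})")
        plus_t = tpos if self.strand == "+" else self.length - 1 - tpos
        offset = 0
        for s, e in self.exons:
            if plus_t < offset + (e - s):
                return s + (plus_t - offset)
            offset += e - s
        raise AssertionError("unreachable")

    def region_of(self, tpos: int) -> str:
        """Region label (5UTR/CDS/3UTR) of a transcript position."""
        if not 0 <= tpos < self.length:
            raise ValueError(f"transcript position {tpos} outside [0, {self.length})")
        if not self.is_coding:
            return "ncRNA_exonic"
        if tpos < self.cds_start:
            return "5UTR"
        if tpos < self.cds_end:
            return "CDS"
        return "3UTR"

    def spliced_sequence(self, genome) -> str:
        """Mature-mRNA sequence (DNA alphabet, sense strand)."""
        seq = "".join(str(genome[self.chrom][s:e]) for s, e in self.exons)
        if self.strand == "-":
            seq = revcomp(seq)
        return seq


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ----------------------------------------------------------------------
# BED12 round trip.  thickStart/thickEnd carry the CDS in genome space.

def write_bed12(models: Iterable[TranscriptModel], path) -> None:
    with open(path, "w") as fh:
        for m in models:
            start, end = m.span
            if m.is_coding:
                g1 = m.transcript_to_genomic(m.cds_start)
                g2 = m.transcript_to_genomic(m.cds_end - 1)
                thick_start, thick_end = min(g1, g2), max(g1, g2) + 1
            else:
                thick_start = thick_end = start
            sizes = ",".join(str(e - s) for s, e in m.exons)
            starts = ",".join(str(s - start) for s, e in m.exons)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        m.chrom, start, end,
                        f"{m.transcript_id}|{m.gene_id}|{m.biotype}",
                        0, m.strand, thick_start, thick_end, "0,0,0",
                        len(m.exons), sizes, starts,
                    )
                )
                + "\n"
            )


def read_bed12(path) -> list[TranscriptModel]:
    models = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start = f[0], int(f[1])
            name_parts = f[3].split("|")
            tid = name_parts[0]
            gid = name_parts[1] if len(name_parts) > 1 else tid
            biotype = name_parts[2] if len(name_parts) > 2 else "protein_coding"
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            m = TranscriptModel(tid, gid, chrom, strand, exons, biotype=biotype)
            if thick_end > thick_start:
                t1 = m.genomic_to_transcript(thick_start)
                t2 = m.genomic_to_transcript(thick_end - 1)
                cds_start, cds_end = min(t1, t2), max(t1, t2) + 1
                m = TranscriptModel(tid, gid, chrom, strand, exons,
                                    cds_start=cds_start, cds_end=cds_end,
                                    biotype=biotype)
            else:
                m.biotype = biotype if biotype != "protein_coding" else "ncRNA"
            models.append(m)
    return models
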