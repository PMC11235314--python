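"""Per-cytosine conversion evidence from bisulfite alignments.

Bisulfite treatment deaminates unmethylated cytosine to uracil, which is
sequenced as T; methylated cytosines stay C.  On forward reads the evidence
therefore lives at reference C positions (C = non-converted, T = converted);
on reverse reads at reference G positions (G = non-converted, A = converted).

Two read-level quality rules precede counting: bases below a minimum base
quality are ignored, and bases within a fixed distance of either read end
are masked (end trimming avoids inflated non-conversion at fragment ends).
A further artifact filter (the "3C filter") discards whole reads that carry
more than three non-converted cytosines, which are typically conversion
failures in structured regions rather than genuine methylation.

Counts are held in a pandas DataFrame with one row per (chrom, pos0, strand)
cytosine and the column set ``COUNT_COLUMNS``.  Coordinates are 0-based
half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "COUNT_COLUMNS",
    "CytosineCount",
    "ReadRecord",
    "read_3c_filter",
    "count_cytosines",
    "apply_3c",
    "signal_to_noise",
    "global_conversion_rate",
    "pbc1",
]

#: fixed column order of a count table
COUNT_COLUMNS = [
    "chrom", "pos0", "strand",
    "nonconv_raw", "conv_raw", "other_raw",
    "nonconv_3c", "conv_3c", "other_3c",
]

KEY_COLUMNS = ["chrom", "pos0", "strand"]
RAW_COLUMNS = ["nonconv_raw", "conv_raw", "other_raw"]
POST3C_COLUMNS = ["nonconv_3c", "conv_3c", "other_3c"]

MAX_NONCONVERTED_PER_READ = 3  # the "3C" read filter boundary ("more than three")


@dataclass
class CytosineCount:
    """Evidence at a single cytosine (scalar convenience mirror of a table row)."""

    chrom: str
    pos0: int
    strand: str
    nonconv_raw: int = 0
    conv_raw: int = 0
    other_raw: int = 0
    nonconv_3c: int = 0
    conv_3c: int = 0
    other_3c: int = 0

    def __post_init__(self):
        for c in RAW_COLUMNS + POST3C_COLUMNS:
            if getattr(self, c) < 0:
                raise ValueError(f"{c} must be non-negative")

    @property
    def coverage_raw(self) -> int:
        return self.nonconv_raw + self.conv_raw + self.other_raw

    @property
    def coverage_3c(self) -> int:
        return self.nonconv_3c + self.conv_3c + self.other_3c


@dataclass
class ReadRecord:
    """Cytosine observations of one read after quality/end-trim masking.

    ``observations`` is a list of ``(position, non_converted)`` pairs at
    reference cytosines (strand-aware), strictly increasing in position.
    """

    read_id: str
    chrom: str
    strand: str
    observations: list[tuple[int, bool]] = field(default_factory=list)

    def __post_init__(self):
        pos = [p for p, _ in self.observations]
        if any(b >= a for a, b in zip(pos[1:], pos)):
            raise ValueError("observation positions must be strictly increasing")

    @property
    def n_nonconverted(self) -> int:
        return sum(1 for _, nc in self.observations if nc)


def read_3c_filter(read: ReadRecord) -> bool:
    """True if the read is kept: at most three non-converted cytosines."""
    return read.n_nonconverted <= MAX_NONCONVERTED_PER_READ


# ----------------------------------------------------------------------
# alignment parsing

def _ref_base(genome, chrom: str, pos: int) -> str:
    try:
        seq = genome[chrom]
    except KeyError:
        raise KeyError(f"reference contig {chrom!r} missing from genome") from None
    return str(seq[pos]).upper()


def count_cytosines(
    alignments,
    genome,
    min_base_quality: int = 30,
    end_trim: int = 6,
    min_mapping_quality: int = 1,
) -> tuple[pd.DataFrame, list[ReadRecord]]:
    """Tally strand-aware conversion evidence from aligned reads.

    Parameters
    ----------
    alignments
        Path to a SAM/BAM file or an open ``pysam.AlignmentFile``.
    genome
        Mapping of contig name to sequence (a dict of strings or a
        ``pyfaidx.Fasta``).
    min_base_quality
        Bases below this Phred quality are ignored (default 30).
    end_trim
        Bases within this many nt of either read end are masked (default 6,
        applied to both ends).
    min_mapping_quality
        Reads below this MAPQ, or flagged secondary/supplementary, are
        treated as not uniquely mapped and skipped.

    Returns
    -------
    (counts, reads)
        ``counts``: raw-field count table (post-3C columns primed equal to
        raw; pass the pair to :func:`apply_3c` to recompute them).
        ``reads``: per-read observation records feeding the 3C filter.
    """
    import pysam

    own = False
    if not hasattr(alignments, "fetch"):
        alignments = pysam.AlignmentFile(str(alignments), check_sq=False)
        own = True
    tally: dict[tuple[str, int, str], list[int]] = {}
    reads: list[ReadRecord] = []
    seen_fragment: dict[tuple[str, str, int, str], None] = {}
    try:
        for aln in alignments.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapping_quality:
                continue
            strand = "-" if aln.is_reverse else "+"
            ref_non, ref_conv = ("C", "T") if strand == "+" else ("G", "A")
            quals = aln.query_qualities
            seq = aln.query_sequence
            if seq is None:
                continue
            qlen = len(seq)
            obs: list[tuple[int, bool, str]] = []
            for qpos, rpos in aln.get_aligned_pairs(matches_only=True):
                if qpos < end_trim or qpos >= qlen - end_trim:
                    continue
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                ref = _ref_base(genome, aln.reference_name, rpos)
                if ref != ref_non:
                    continue
                base = seq[qpos].upper()
                if base == ref_non:
                    obs.append((rpos, True, "nonconv"))
                elif base == ref_conv:
                    obs.append((rpos, False, "conv"))
                else:
                    obs.append((rpos, False, "other"))
            # first-mate precedence for overlapping paired-end fragments
            if aln.is_paired and aln.is_read2:
                frag = (aln.query_name, aln.reference_name, 0, strand)
                mate_key = seen_fragment.get(frag)
                if mate_key is not None:
                    obs = [o for o in obs if o[0] not in mate_key]
            if aln.is_paired and aln.is_read1:
                seen_fragment[(aln.query_name, aln.reference_name, 0, strand)] = {
                    o[0] for o in obs
                }
            rec = ReadRecord(
                aln.query_name, aln.reference_name, strand,
                [(p, nc) for p, nc, _ in obs],
            )
            reads.append(rec)
            for rpos, _, kind in obs:
                key = (aln.reference_name, rpos, strand)
                row = tally.setdefault(key, [0, 0, 0])
                row["nonconv conv other".split().index(kind)] += 1
    finally:
        if own:
            alignments.close()

    rows = [
        {
            "chrom": c, "pos0": p, "strand": s,
            "nonconv_raw": v[0], "conv_raw": v[1], "other_raw": v[2],
            "nonconv_3c": v[0], "conv_3c": v[1], "other_3c": v[2],
        }
        for (c, p, s), v in sorted(tally.items())
    ]
    counts = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return counts, reads


# ----------------------------------------------------------------------
# 3C filter

def apply_3c(counts_raw: pd.DataFrame, reads: Iterable[ReadRecord]) -> pd.DataFrame:
    """Recompute post-3C tallies by removing reads failing the 3C filter.

    Post-3C columns start from the raw columns and the observations of every
    discarded read (more than three non-converted cytosines) are subtracted.
    Idempotent: post-3C fields are always derived from the raw fields.
    """
    out = counts_raw.copy()
    out[["nonconv_3c", "conv_3c", "other_3c"]] = out[RAW_COLUMNS].to_numpy()
    discarded = [r for r in reads if not read_3c_filter(r)]
    if len(out) == 0 or not discarded:
        return out
    idx = {
        (c, p, s): i
        for i, (c, p, s) in enumerate(zip(out["chrom"], out["pos0"], out["strand"]))
    }
    nonconv = out["nonconv_3c"].to_numpy().copy()
    conv = out["conv_3c"].to_numpy().copy()
    for read in discarded:
        for pos, nc in read.observations:
            i = idx.get((read.chrom, pos, read.strand))
            if i is None:
                continue
            if nc:
                nonconv[i] -= 1
            else:
                conv[i] -= 1
    out["nonconv_3c"] = np.maximum(nonconv, 0)
    out["conv_3c"] = np.maximum(conv, 0)
    return out


def signal_to_noise(counts: pd.DataFrame) -> pd.Series:
    """Fraction of reads surviving the 3C filter (post-3C / raw coverage).

    Positions with zero raw coverage are flagged as no-coverage (NaN).
    """
    raw = counts[RAW_COLUMNS].sum(axis=1).astype(float)
    post = counts[POST3C_COLUMNS].sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        s2n = post / raw
    s2n[raw == 0] = np.nan
    return s2n


# ----------------------------------------------------------------------
# QC metrics

def global_conversion_rate(counts: pd.DataFrame, use_raw: bool = True) -> float:
    """Overall C-to-T conversion: converted / (converted + non-converted)."""
    if len(counts) == 0:
        raise ValueError("conversion rate undefined on an empty selection")
    cols = ("conv_raw", "nonconv_raw") if use_raw else ("conv_3c", "nonconv_3c")
    conv = int(counts[cols[0]].sum())
    nonconv = int(counts[cols[1]].sum())
    if conv + nonconv == 0:
        raise ValueError("no converted or non-converted reads in selection")
    return conv / (conv + nonconv)


def pbc1(location_read_counts: Iterable[int] | Mapping[object, int]) -> float:
    """PCR Bottlenecking Coefficient 1.

    Number of genomic locations covered by exactly one uniquely mapping read
    divided by the number of distinct locations covered at all.
    """
    if isinstance(location_read_counts, Mapping):
        values = list(location_read_counts.values())
    else:
        values = list(location_read_counts)
    values = [v for v in values if v > 0]
    if not values:
        raise ValueError("PBC1 undefined with no covered locations")
    return sum(1 for v in values if v == 1) / len(values)
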