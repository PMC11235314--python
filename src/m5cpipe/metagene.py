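"""Site annotation, metagene scaling and codon-anchored spatial enrichment.

Mature-mRNA metagene coordinates concatenate the three regions after scaling
each to the mean length of that region across the transcript set (or to
explicitly supplied means, e.g. 5'UTR 270 nt / CDS 2,058 nt / 3'UTR 1,817 nt
for reproducing published profiles).  Background curves are always built
from all cytosines of the same transcripts as the sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .transcripts import TranscriptModel

__all__ = [
    "FEATURE_PRIORITY",
    "annotate_site",
    "MetageneCoordinate",
    "metagene_position",
    "mean_region_lengths",
    "metagene_density",
    "startstop_enrichment",
]

FEATURE_PRIORITY = ["5UTR", "CDS", "3UTR", "ncRNA_exonic", "intronic", "intergenic"]


def annotate_site(
    chrom: str,
    pos: int,
    strand: str,
    models: Sequence[TranscriptModel],
) -> tuple[str, set[str]]:
    """Feature annotation of one site against a transcript set.

    All overlapping features are computed (a site can be exonic in one
    isoform and intronic in another); the reported label is the highest in
    the fixed priority 5'UTR > CDS > 3'UTR > ncRNA_exonic > intronic >
    intergenic.  Returns ``(label, all_labels)``.
    """
    labels: set[str] = set()
    for m in models:
        if m.chrom != chrom or m.strand != strand:
            continue
        lo, hi = m.span
        if not lo <= pos < hi:
            continue
        tpos = m.genomic_to_transcript(pos)
        if tpos is None:
            labels.add("intronic")
        else:
            labels.add(m.region_of(tpos))
    if not labels:
        labels = {"intergenic"}
    primary = min(labels, key=FEATURE_PRIORITY.index)
    return primary, labels


@dataclass(frozen=True)
class MetageneCoordinate:
    region: str           # 5UTR | CDS | 3UTR
    fraction: float       # position within the region, in [0, 1]
    scaled: float         # position on the concatenated scaled axis, nt


def mean_region_lengths(models: Iterable[TranscriptModel]) -> tuple[float, float, float]:
    """Mean 5'UTR / CDS / 3'UTR length over the coding transcripts."""
    u5, cds, u3 = [], [], []
    for m in models:
        if m.is_coding:
            u5.append(m.utr5_length)
            cds.append(m.cds_length)
            u3.append(m.utr3_length)
    if not cds:
        raise ValueError("no coding transcripts")
    return float(np.mean(u5)), float(np.mean(cds)), float(np.mean(u3))


def metagene_position(
    site_pos: int,
    transcript: TranscriptModel,
    region_means: tuple[float, float, float],
    genomic: bool = True,
) -> MetageneCoordinate:
    """Scaled metagene coordinate of a mature-mRNA site.

    ``site_pos`` is genomic (default) or already a transcript offset
    (``genomic=False``).  The fractional position within the region uses the
    closed-interval convention ``(pos - region_start) / (region_len - 1)``,
    so the first nt of the 5'UTR maps to 0 and the last nt of the 3'UTR to
    the full scaled length.  Intronic positions raise ``ValueError``.
    """
    if not transcript.is_coding:
        raise ValueError("metagene coordinates require a coding transcript")
    if genomic:
        tpos = transcript.genomic_to_transcript(site_pos)
        if tpos is None:
            raise ValueError(
                f"position {site_pos} is not on the mature mRNA of "
                f"{transcript.transcript_id}"
            )
    else:
        tpos = site_pos
    region = transcript.region_of(tpos)
    bounds = {
        "5UTR": (0, transcript.utr5_length),
        "CDS": (transcript.cds_start, transcript.cds_length),
        "3UTR": (transcript.cds_end, transcript.utr3_length),
    }
    start, length = bounds[region]
    if length <= 1:
        frac = 0.5
    else:
        frac = (tpos - start) / (length - 1)
    m5, mc, m3 = region_means
    offset = {"5UTR": 0.0, "CDS": m5, "3UTR": m5 + mc}[region]
    mean_len = {"5UTR": m5, "CDS": mc, "3UTR": m3}[region]
    return MetageneCoordinate(region, frac, offset + frac * mean_len)


def metagene_density(
    site_scaled: Sequence[float],
    background_scaled: Sequence[float],
    region_means: tuple[float, float, float],
    n_bins: int = 100,
) -> pd.DataFrame:
    """Binned site and background densities on the scaled metagene axis.

    Both curves use identical binning and are normalised so the bin masses
    sum to one.
    """
    site_scaled = np.asarray(site_scaled, float)
    background_scaled = np.asarray(background_scaled, float)
    if site_scaled.size == 0:
        raise ValueError("no sites supplied")
    if background_scaled.size == 0:
        raise ValueError("no background cytosines supplied")
    total = float(sum(region_means))
    edges = np.linspace(0.0, total, n_bins + 1)
    site_hist, _ = np.histogram(np.clip(site_scaled, 0, total), bins=edges)
    bg_hist, _ = np.histogram(np.clip(background_scaled, 0, total), bins=edges)
    return pd.DataFrame(
        {
            "bin_start": edges[:-1],
            "bin_end": edges[1:],
            "site_density": site_hist / site_hist.sum(),
            "background_density": bg_hist / bg_hist.sum(),
        }
    )


def startstop_enrichment(
    site_offsets: Sequence[float],
    background_offsets: Sequence[float],
    window: int = 300,
    bin_width: int = 50,
) -> pd.DataFrame:
    """Per-bin observed/expected enrichment of sites around a codon.

    Offsets are positions relative to the start (or stop) codon in mature
    mRNA coordinates.  Each bin is tested with a 2x2 chi-squared of (sites
    in/out of bin) vs (background C in/out of bin); enrichment is
    ``(sites_in / sites_total) / (bg_in / bg_total)``.  Bins without
    background cytosines report a missing enrichment.
    """
    site_offsets = np.asarray(site_offsets, float)
    background_offsets = np.asarray(background_offsets, float)
    if site_offsets.size == 0:
        raise ValueError("no sites supplied")
    if background_offsets.size == 0:
        raise ValueError("no background cytosines supplied")
    edges = np.arange(-window, window + bin_width, bin_width)
    s_hist, _ = np.histogram(site_offsets, bins=edges)
    b_hist, _ = np.histogram(background_offsets, bins=edges)
    s_tot, b_tot = site_offsets.size, background_offsets.size
    rows = []
    for k in range(len(edges) - 1):
        s_in, b_in = int(s_hist[k]), int(b_hist[k])
        if b_in == 0:
            enr, p = np.nan, np.nan
        else:
            enr = (s_in / s_tot) / (b_in / b_tot)
            table = np.array([[s_in, s_tot - s_in], [b_in, b_tot - b_in]])
            if table.min() < 0 or (table.sum(axis=1) == 0).any():
                p = np.nan
            else:
                p = float(stats.chi2_contingency(table, correction=False)[1]) \
                    if (table.sum(axis=0) > 0).all() else np.nan
        rows.append(
            {"bin_start": int(edges[k]), "bin_end": int(edges[k + 1]),
             "n_sites": s_in, "n_background": b_in,
             "enrichment": enr, "chi2_p": p}
        )
    return pd.DataFrame(rows)
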