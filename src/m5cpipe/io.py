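"""Plain-text readers/writers for the pipeline's tabular interfaces.

Count tables and ground truth travel as TSV, transcripts as BED12, called
sites as BED6+ (score = 1000 x methylation level), footprints as
narrowPeak-compatible BED6+4.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .counting import COUNT_COLUMNS

__all__ = [
    "write_fasta", "read_fasta",
    "write_counts", "read_counts",
    "write_sites_bed", "read_narrowpeak", "write_narrowpeak",
]


def write_fasta(genome: Mapping[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i: i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.loc[:, COUNT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df.loc[:, COUNT_COLUMNS]


def write_sites_bed(sites: pd.DataFrame, path, name_column: str | None = None) -> None:
    """Called sites as BED6+: name = gene if annotated, score = 1000 x level."""
    with open(path, "w") as fh:
        for _, r in sites.iterrows():
            name = r[name_column] if name_column and name_column in r else "m5C"
            level = r.get("level", float("nan"))
            score = int(round(1000 * level)) if pd.notna(level) else 0
            fh.write(
                f"{r['chrom']}\t{int(r['pos0'])}\t{int(r['pos0']) + 1}\t"
                f"{name}\t{score}\t{r['strand']}\t{level:.4f}\n"
            )


_NARROWPEAK_COLUMNS = ["chrom", "start", "end", "name", "score", "strand",
                       "fold_enrichment", "p_value_log10", "q_value_log10", "peak"]


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    import numpy as np

    with open(path, "w") as fh:
        for _, r in peaks.iterrows():
            p = r.get("p_value", float("nan"))
            plog = -np.log10(p) if p and p > 0 else -1
            fh.write(
                f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t"
                f"{r.get('name', '.')}\t{int(r.get('score', 0))}\t{r.get('strand', '.')}\t"
                f"{r['fold_enrichment']:.4f}\t{plog:.4f}\t-1\t-1\n"
            )


def read_narrowpeak(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=_NARROWPEAK_COLUMNS)
    df["p_value"] = 10.0 ** (-df["p_value_log10"])
    return df
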