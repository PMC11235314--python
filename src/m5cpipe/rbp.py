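"""Co-enrichment of m5C sites with RBP eCLIP footprints.

Footprints from two biological replicates are intersected and filtered
(fold-enrichment >= 4, p <= 1e-3); each retained footprint is anchored at
its interval midpoint.  On genes carrying both a footprint and an m5C site,
the distribution of m5C versus unmodified cytosines inside and outside
+/-half-width windows around the anchors forms a 2x2 table tested with
Fisher's exact test (chi-squared is also reported), with BH-FDR adjustment
across RBPs.  All positions here are mature-mRNA (spliced) coordinates, the
'chrom' field naming the transcript/gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "filter_footprints",
    "window_enrichment",
    "EnrichmentResult",
    "fdr_adjust",
    "offset_density",
    "five_category_grouping",
    "group_expression_shift",
]

FOOTPRINT_COLUMNS = ["chrom", "start", "end", "strand", "fold_enrichment", "p_value"]


def footprint_center(start: int, end: int) -> int:
    """Midpoint of a half-open interval; left-median for even lengths."""
    return (start + end - 1) // 2


def filter_footprints(
    rep1: pd.DataFrame,
    rep2: pd.DataFrame,
    min_fold: float = 4.0,
    max_p: float = 1e-3,
) -> pd.DataFrame:
    """Replicate-intersected, thresholded footprints with centre anchors.

    A footprint is retained when an interval in replicate 1 overlaps one in
    replicate 2 and both carry fold-enrichment >= ``min_fold`` and p-value
    <= ``max_p`` (boundaries inclusive).  The reported interval is the
    intersection; the evidence columns keep the weaker replicate (min fold,
    max p).
    """
    if rep1 is None or rep2 is None:
        raise ValueError("both replicates are required")
    rows = []
    r2_by_key: dict[tuple, pd.DataFrame] = {
        k: g.sort_values("start") for k, g in rep2.groupby(["chrom", "strand"])
    }
    for _, a in rep1.iterrows():
        g = r2_by_key.get((a["chrom"], a["strand"]))
        if g is None:
            continue
        overlap = g[(g["start"] < a["end"]) & (g["end"] > a["start"])]
        for _, b in overlap.iterrows():
            fold = min(a["fold_enrichment"], b["fold_enrichment"])
            p = max(a["p_value"], b["p_value"])
            if fold >= min_fold and p <= max_p:
                start = int(max(a["start"], b["start"]))
                end = int(min(a["end"], b["end"]))
                rows.append(
                    {
                        "chrom": a["chrom"], "start": start, "end": end,
                        "strand": a["strand"], "center": footprint_center(start, end),
                        "fold_enrichment": fold, "p_value": p,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "strand", "center",
                 "fold_enrichment", "p_value"],
    ).drop_duplicates(ignore_index=True)


@dataclass
class EnrichmentResult:
    """One RBP x window half-width contingency table with its tests."""

    rbp: str
    half_width: int
    a: int  # m5C inside windows
    b: int  # background C inside windows
    c: int  # m5C outside windows
    d: int  # background C outside windows
    odds_ratio: float
    p_value: float
    chi2_p: float | None = None
    q_value: float | None = None
    note: str = ""

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


def _flatten_windows(centers: np.ndarray, half_width: int) -> list[tuple[int, int]]:
    """Union of closed intervals [c - h, c + h] (no double counting)."""
    ivs = sorted((int(c) - half_width, int(c) + half_width) for c in centers)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(x) for x in merged]


def _count_in_windows(pos: np.ndarray, windows: list[tuple[int, int]]) -> int:
    if pos.size == 0 or not windows:
        return 0
    inside = np.zeros(pos.shape, dtype=bool)
    for s, e in windows:
        inside |= (pos >= s) & (pos <= e)
    return int(inside.sum())


def window_enrichment(
    sites: pd.DataFrame,
    background: pd.DataFrame,
    footprints: pd.DataFrame,
    half_width: int = 50,
    rbp: str = "",
) -> EnrichmentResult:
    """Fisher test of m5C density inside +/-half_width of footprint centres.

    ``sites`` and ``background`` need columns ``chrom`` (transcript/gene id)
    and ``pos`` (mature-mRNA coordinate); ``footprints`` is the output of
    :func:`filter_footprints` (or any frame with ``chrom``/``center``).
    Only genes carrying at least one site *and* one footprint enter the
    table.  Window membership is ``|pos - center| <= half_width``;
    overlapping windows are flattened before counting.
    """
    site_genes = set(sites["chrom"].unique())
    fp_genes = set(footprints["chrom"].unique())
    genes = site_genes & fp_genes
    if not genes:
        return EnrichmentResult(rbp, half_width, 0, 0, 0, 0, np.nan, np.nan,
                                note="no genes with both footprints and m5C sites")
    a = b = c = d = 0
    fp_by_gene = dict(tuple(footprints.groupby("chrom")))
    site_by_gene = dict(tuple(sites.groupby("chrom")))
    bg_by_gene = dict(tuple(background.groupby("chrom")))
    for gene in genes:
        windows = _flatten_windows(fp_by_gene[gene]["center"].to_numpy(), half_width)
        spos = site_by_gene[gene]["pos"].to_numpy()
        bpos = (bg_by_gene[gene]["pos"].to_numpy()
                if gene in bg_by_gene else np.empty(0, int))
        a_in = _count_in_windows(spos, windows)
        b_in = _count_in_windows(bpos, windows)
        a += a_in
        c += spos.size - a_in
        b += b_in
        d += bpos.size - b_in
    if b * c > 0:
        odds = (a * d) / (b * c)
    else:
        odds = np.inf if a * d > 0 else np.nan
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    table = np.array([[a, b], [c, d]])
    if (table.sum(axis=0) > 0).all() and (table.sum(axis=1) > 0).all():
        chi2_p = float(stats.chi2_contingency(table, correction=False)[1])
    else:
        chi2_p = np.nan
    return EnrichmentResult(rbp, half_width, a, b, c, d, odds, p, chi2_p)


def fdr_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def offset_density(
    sites: pd.DataFrame,
    background: pd.DataFrame,
    footprints: pd.DataFrame,
    max_offset: int = 100,
    bin_width: int = 5,
) -> pd.DataFrame:
    """Density of m5C and background C versus signed offset from centres.

    Every (position, footprint centre) pair on the same gene with
    ``|offset| <= max_offset`` contributes; both curves share the binning
    and are normalised to unit mass.
    """
    if len(footprints) == 0:
        raise ValueError("no footprints supplied")
    edges = np.arange(-max_offset, max_offset + bin_width, bin_width)

    def _offsets(table: pd.DataFrame) -> np.ndarray:
        out = []
        fp_by_gene = dict(tuple(footprints.groupby("chrom")))
        for gene, g in table.groupby("chrom"):
            if gene not in fp_by_gene:
                continue
            centers = fp_by_gene[gene]["center"].to_numpy()
            diff = g["pos"].to_numpy()[:, None] - centers[None, :]
            out.append(diff[np.abs(diff) <= max_offset])
        return np.concatenate(out) if out else np.empty(0)

    s_off, b_off = _offsets(sites), _offsets(background)
    s_hist, _ = np.histogram(s_off, bins=edges)
    b_hist, _ = np.histogram(b_off, bins=edges)
    return pd.DataFrame(
        {
            "offset": (edges[:-1] + edges[1:]) / 2.0,
            "site_density": s_hist / max(s_hist.sum(), 1),
            "background_density": b_hist / max(b_hist.sum(), 1),
        }
    )


def five_category_grouping(
    genes: Sequence[str],
    footprints: pd.DataFrame,
    sites: pd.DataFrame,
    half_width: int = 50,
) -> pd.Series:
    """Partition the transcriptome by RBP binding and writer-specific m5C.

    Categories: I neither; II m5C site only; III footprint only; IV both but
    every site farther than ``half_width`` from every footprint centre; V
    both with at least one site within ``half_width`` ("in region").  Every
    gene receives exactly one category.
    """
    fp_by_gene = dict(tuple(footprints.groupby("chrom")))
    site_by_gene = dict(tuple(sites.groupby("chrom")))
    out = {}
    for gene in genes:
        has_fp = gene in fp_by_gene
        has_site = gene in site_by_gene
        if not has_fp and not has_site:
            out[gene] = "I"
        elif has_site and not has_fp:
            out[gene] = "II"
        elif has_fp and not has_site:
            out[gene] = "III"
        else:
            centers = fp_by_gene[gene]["center"].to_numpy()
            pos = site_by_gene[gene]["pos"].to_numpy()
            near = np.abs(pos[:, None] - centers[None, :]) <= half_width
            out[gene] = "V" if near.any() else "IV"
    return pd.Series(out, name="category")


def group_expression_shift(
    de_table: pd.DataFrame,
    categories: pd.Series,
    lfc_column: str = "log2FoldChange",
    min_n: int = 3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-category log-fold-change summaries with pairwise Welch t-tests.

    ``de_table`` is an externally produced differential-expression table
    indexed by gene.  Genes absent from it are excluded (count recorded in
    ``summary.attrs['n_excluded']``); category pairs where either side has
    fewer than ``min_n`` genes are skipped with a note.
    """
    cats = categories.dropna()
    present = cats.index.intersection(de_table.index)
    n_excluded = len(cats) - len(present)
    lfc = de_table.loc[present, lfc_column].astype(float)
    groups = {c: lfc[cats.loc[present] == c].to_numpy() for c in sorted(cats.unique())}
    summary = pd.DataFrame(
        [
            {"category": c, "n": v.size,
             "mean_lfc": float(np.mean(v)) if v.size else np.nan,
             "median_lfc": float(np.median(v)) if v.size else np.nan}
            for c, v in groups.items()
        ]
    )
    summary.attrs["n_excluded"] = n_excluded
    rows = []
    names = list(groups)
    for i, ca in enumerate(names):
        for cb in names[i + 1:]:
            va, vb = groups[ca], groups[cb]
            if va.size < min_n or vb.size < min_n:
                rows.append({"category_a": ca, "category_b": cb,
                             "t": np.nan, "p_value": np.nan,
                             "note": f"skipped: n<{min_n}"})
                continue
            t, p = stats.ttest_ind(va, vb, equal_var=False)
            rows.append({"category_a": ca, "category_b": cb,
                         "t": float(t), "p_value": float(p), "note": ""})
    return summary, pd.DataFrame(rows)
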