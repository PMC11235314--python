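"""m5C candidate filtering, replicate integration and union-set building.

The filter cascade retains a cytosine as a candidate site when, after the
read-level 3C filter:

* signal-to-noise (post-3C / raw coverage) >= 0.9        ("S/N90")
* total read coverage >= 20                              ("20RC")
* non-converted reads >= 3                               ("3C" count)
* C+T fraction of coverage >= 0.8                        ("80CT")
* non-conversion ratio >= 0.10                           ("10MM")

All boundaries are inclusive.  The non-conversion ratio uses the C+T
coverage as denominator (other bases are treated as a separate contamination
signal caught by 80CT).  A site is finally called when it passes in at least
two replicates, or in exactly one replicate with >= 5 non-converted reads.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .counting import CytosineCount, POST3C_COLUMNS, RAW_COLUMNS

__all__ = [
    "CallThresholds",
    "call_candidates",
    "call_candidate",
    "integrate_replicates",
    "merge_union",
    "classify_shared_site",
    "SamplePairClass",
]

KEY = ["chrom", "pos0", "strand"]


@dataclass(frozen=True)
class CallThresholds:
    min_coverage: int = 20        # 20RC
    min_nonconv: int = 3          # "3C" count criterion
    min_ratio: float = 0.10       # 10MM
    min_ct_fraction: float = 0.80  # 80CT
    min_s2n: float = 0.90         # S/N90
    single_rep_min_nonconv: int = 5


def call_candidates(counts: pd.DataFrame, thresholds: CallThresholds | None = None) -> pd.DataFrame:
    """Apply the per-replicate filter cascade to a count table.

    Returns a copy of ``counts`` with derived columns (coverage, ratio,
    ct_fraction, s2n), one boolean column per filter, and ``passes``.
    Positions with zero C+T coverage are not callable: flags are False and
    the ratio is NaN, but no exception is raised.
    """
    t = thresholds or CallThresholds()
    out = counts.copy()
    cov_raw = out[RAW_COLUMNS].sum(axis=1).to_numpy(float)
    cov_3c = out[POST3C_COLUMNS].sum(axis=1).to_numpy(float)
    nonconv = out["nonconv_3c"].to_numpy(float)
    cov_ct = nonconv + out["conv_3c"].to_numpy(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(cov_ct > 0, nonconv / np.where(cov_ct > 0, cov_ct, 1), np.nan)
        ct_fraction = np.where(cov_3c > 0, cov_ct / np.where(cov_3c > 0, cov_3c, 1), np.nan)
        s2n = np.where(cov_raw > 0, cov_3c / np.where(cov_raw > 0, cov_raw, 1), np.nan)

    out["coverage"] = cov_3c
    out["coverage_ct"] = cov_ct
    out["ratio"] = ratio
    out["ct_fraction"] = ct_fraction
    out["s2n"] = s2n
    callable_ = cov_ct > 0
    out["pass_S2N"] = callable_ & (s2n >= t.min_s2n)
    out["pass_20RC"] = callable_ & (cov_3c >= t.min_coverage)
    out["pass_3Ccount"] = callable_ & (nonconv >= t.min_nonconv)
    out["pass_80CT"] = callable_ & (ct_fraction >= t.min_ct_fraction)
    out["pass_10MM"] = callable_ & (ratio >= t.min_ratio)
    out["passes"] = (
        out["pass_S2N"] & out["pass_20RC"] & out["pass_3Ccount"]
        & out["pass_80CT"] & out["pass_10MM"]
    )
    return out


def call_candidate(count: CytosineCount, thresholds: CallThresholds | None = None) -> dict:
    """Scalar convenience wrapper around :func:`call_candidates`."""
    df = pd.DataFrame(
        [{k: getattr(count, k) for k in
          ["chrom", "pos0", "strand"] + RAW_COLUMNS + POST3C_COLUMNS}]
    )
    return call_candidates(df, thresholds).iloc[0].to_dict()


def integrate_replicates(
    replicates: Sequence[pd.DataFrame],
    thresholds: CallThresholds | None = None,
) -> pd.DataFrame:
    """Combine per-replicate candidate tables into final site calls.

    ``replicates`` are outputs of :func:`call_candidates` (one per biological
    replicate).  A site is called when it passes all per-replicate filters in
    >= 2 replicates, or in exactly one replicate whose non-converted read
    count reaches the stricter single-replicate floor (>= 5).

    The reported methylation level pools non-converted and C+T coverage over
    the passing replicates.
    """
    t = thresholds or CallThresholds()
    if not replicates:
        raise ValueError("at least one replicate required")
    pieces = []
    for i, rep in enumerate(replicates):
        sub = rep.loc[:, KEY + ["nonconv_3c", "coverage_ct", "coverage", "passes"]].copy()
        sub["replicate"] = i
        pieces.append(sub)
    long = pd.concat(pieces, ignore_index=True)
    # only positions passing in >=1 replicate can ever be called; restricting
    # to them keeps integration cheap on transcriptome-scale tables
    candidates = long.loc[long["passes"], KEY].drop_duplicates()
    long = long.merge(candidates, on=KEY, how="inner")
    if long.empty:
        return pd.DataFrame(
            columns=KEY + ["n_replicates_passing", "final_call", "level", "coverage_mean"]
        )

    def _agg(g: pd.DataFrame) -> pd.Series:
        passing = g[g["passes"]]
        n_pass = len(passing)
        if n_pass >= 2:
            called = True
        elif n_pass == 1:
            called = bool(passing["nonconv_3c"].iloc[0] >= t.single_rep_min_nonconv)
        else:
            called = False
        pool = passing if n_pass else g
        ct = pool["coverage_ct"].sum()
        level = pool["nonconv_3c"].sum() / ct if ct > 0 else np.nan
        return pd.Series(
            {
                "n_replicates_passing": n_pass,
                "final_call": called,
                "level": level,
                "coverage_mean": g["coverage"].mean(),
            }
        )

    out = long.groupby(KEY, sort=True).apply(_agg, include_groups=False).reset_index()
    out["n_replicates_passing"] = out["n_replicates_passing"].astype(int)
    out["final_call"] = out["final_call"].astype(bool)
    return out


def merge_union(
    site_tables: Mapping[str, pd.DataFrame],
    genome_builds: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Deduplicated union of called sites across samples.

    ``site_tables`` maps sample name to a table of *called* sites (rows with
    ``final_call`` True are kept if the column is present; otherwise all rows
    are treated as calls).  Per-sample level and coverage are retained as
    ``level_<sample>`` / ``coverage_<sample>`` columns and the calling
    samples are recorded in ``called_in``.
    """
    if genome_builds:
        builds = set(genome_builds.values())
        if len(builds) > 1:
            raise ValueError(f"genome build mismatch between inputs: {sorted(builds)}")
    merged: pd.DataFrame | None = None
    for sample, tab in site_tables.items():
        sub = tab[tab["final_call"]] if "final_call" in tab.columns else tab
        cols = {}
        if "level" in sub.columns:
            cols[f"level_{sample}"] = sub["level"].to_numpy()
        for c in ("coverage_mean", "coverage"):
            if c in sub.columns:
                cols[f"coverage_{sample}"] = sub[c].to_numpy()
                break
        piece = sub.loc[:, KEY].copy()
        for k, v in cols.items():
            piece[k] = v
        piece = piece.drop_duplicates(subset=KEY)
        piece[f"called_{sample}"] = True
        merged = piece if merged is None else merged.merge(piece, on=KEY, how="outer")
    if merged is None:
        return pd.DataFrame(columns=KEY)
    call_cols = [c for c in merged.columns if c.startswith("called_")]
    for c in call_cols:
        merged[c] = merged[c].eq(True)
    merged["called_in"] = merged[call_cols].apply(
        lambda r: ",".join(c[len("called_"):] for c in call_cols if r[c]), axis=1
    )
    return merged.sort_values(KEY, kind="stable").reset_index(drop=True)


@dataclass(frozen=True)
class SamplePairClass:
    site_class: str  # common | low_coverage | sub_methylated | non_methylated
    p_value: float | None = None


def classify_shared_site(
    coverage_b: float,
    nonconv_b: float,
    called_b: bool,
    error_rate_b: float,
    min_coverage: int = 20,
) -> SamplePairClass:
    """Explain why a site called in sample A is or is not seen in sample B.

    Decision tree: coverage below 20 -> ``low_coverage``; called in B ->
    ``common``; non-conversion level in [1%, 10%) with a one-sided binomial
    test against B's global non-conversion error rate significant at 0.05 ->
    ``sub_methylated``; otherwise ``non_methylated``.
    """
    if coverage_b < min_coverage:
        return SamplePairClass("low_coverage")
    if called_b:
        return SamplePairClass("common")
    level = nonconv_b / coverage_b if coverage_b > 0 else 0.0
    if 0.01 <= level < 0.10:
        # P(X >= nonconv_b) under Binomial(coverage, error_rate)
        p = float(stats.binom.sf(nonconv_b - 1, int(round(coverage_b)), error_rate_b))
        if p < 0.05:
            return SamplePairClass("sub_methylated", p)
        return SamplePairClass("non_methylated", p)
    return SamplePairClass("non_methylated")
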