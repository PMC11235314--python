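"""Ground-truthed synthetic transcriptomes, methylomes and bisulfite evidence.

The generator emulates the statistical structure the downstream analysis
assumes: transcripts with 5'UTR/CDS/3'UTR architecture drawn around
configurable mean lengths; true m5C sites embedded in writer-specific
sequence contexts (NSUN2: 3' G-rich; NSUN6: CUCCA at offsets 0..+4; NSUN5:
GUNGCCANNUG with the modified C at its fifth base); per-cytosine coverage
from an over-dispersed count distribution; binomially sampled non-conversion
(at the true stoichiometry on sites, at a global conversion-failure rate
elsewhere); read-level "structured" artifact reads carrying clustered
non-conversions for the 3C filter to catch; independent biological
replicates; writer-depletion conditions; and RBP footprints placed with a
controllable enrichment near true sites.

Non-artifact evidence is generated at count level under an equivalent-read
expansion (each coverage unit is one read observing that cytosine, hence
carrying at most one non-converted C and always passing the 3C filter);
artifact reads are emitted as explicit read records because the 3C and S/N
filters are read-level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .counting import COUNT_COLUMNS, ReadRecord
from .transcripts import TranscriptModel

__all__ = [
    "SimConfig",
    "SimConfigError",
    "WRITERS",
    "simulate_transcriptome",
    "simulate_methylome",
    "simulate_pileups",
    "simulate_depletion",
    "simulate_footprints",
    "ReplicatePileup",
    "FootprintSim",
]

WRITERS = ("NSUN2", "NSUN6", "NSUN5", "other")

TRUTH_COLUMNS = ["transcript_id", "chrom", "pos0", "strand", "tpos",
                 "stoichiometry", "writer", "motif"]


class SimConfigError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated study condition.

    Distributions are named tuples ``(name, params)``:
    coverage — ``("negative_binomial", {"mean", "dispersion"})`` (variance
    mean + dispersion * mean^2), ``("poisson", {"mean"})`` or
    ``("constant", {"value"})``; stoichiometry — ``("uniform", {"low",
    "high"})``, ``("beta", {"a", "b"})`` or ``("constant", {"value"})``.
    """

    seed: int = 0
    n_transcripts: int = 200
    region_length_means: tuple[int, int, int] = (270, 2058, 1817)
    n_true_sites: int = 300
    stoichiometry_distribution: tuple = ("uniform", {"low": 0.10, "high": 0.60})
    coverage_distribution: tuple = ("negative_binomial", {"mean": 50.0, "dispersion": 0.5})
    conversion_failure_rate: float = 0.003
    structured_read_fraction: float = 0.005
    n_replicates: int = 2
    writer_mix: dict = field(
        default_factory=lambda: {"NSUN2": 4 / 6, "NSUN6": 1 / 6, "NSUN5": 0.0, "other": 1 / 6}
    )
    footprint_enrichment: float = 0.8

    def validate(self) -> None:
        for name in ("conversion_failure_rate", "structured_read_fraction",
                     "footprint_enrichment"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_transcripts", "n_replicates"):
            if getattr(self, name) <= 0:
                raise SimConfigError(f"{name} must be positive")
        if self.n_true_sites < 0:
            raise SimConfigError("n_true_sites must be non-negative")
        if any(m <= 0 for m in self.region_length_means):
            raise SimConfigError("region length means must be positive")
        if any(w not in WRITERS for w in self.writer_mix):
            raise SimConfigError(f"unknown writer in mix: {self.writer_mix}")
        total = sum(self.writer_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise SimConfigError(f"writer_mix proportions must sum to 1, got {total}")

    def rng(self, stream: int = 0) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


# ----------------------------------------------------------------------
# distribution helpers

def _draw_counts(dist: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    name, params = dist
    if name == "negative_binomial":
        mean, disp = float(params["mean"]), float(params["dispersion"])
        r = 1.0 / disp
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=size)
    if name == "poisson":
        return rng.poisson(float(params["mean"]), size=size)
    if name == "constant":
        return np.full(size, int(params["value"]))
    raise SimConfigError(f"unknown count distribution {name!r}")


def _draw_fractions(dist: tuple, size: int, rng: np.random.Generator) -> np.ndarray:
    name, params = dist
    if name == "uniform":
        return rng.uniform(float(params["low"]), float(params["high"]), size=size)
    if name == "beta":
        return rng.beta(float(params["a"]), float(params["b"]), size=size)
    if name == "constant":
        return np.full(size, float(params["value"]))
    raise SimConfigError(f"unknown fraction distribution {name!r}")


# ----------------------------------------------------------------------
# transcriptome

def simulate_transcriptome(config: SimConfig) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Random genome and transcript models, one contig per transcript.

    Region lengths are gamma-distributed around the configured means
    (shape 4, so CV 0.5), floored at 30 nt (5'UTR, 3'UTR) / 90 nt (CDS);
    CDS lengths are rounded to a multiple of 3.  Sequences are uniform over
    ACGT; reproducible given the seed.
    """
    config.validate()
    rng = config.rng(1)
    m5, mc, m3 = config.region_length_means
    n = config.n_transcripts
    u5 = np.maximum(np.round(rng.gamma(4.0, m5 / 4.0, size=n)), 30).astype(int)
    u3 = np.maximum(np.round(rng.gamma(4.0, m3 / 4.0, size=n)), 30).astype(int)
    cds = np.maximum(np.round(rng.gamma(4.0, mc / 4.0, size=n)), 90).astype(int)
    cds = (cds // 3) * 3
    genome: dict[str, str] = {}
    models: list[TranscriptModel] = []
    for i in range(n):
        length = int(u5[i] + cds[i] + u3[i])
        chrom = f"TX{i:05d}"
        seq = (np.frombuffer(b"ACGT", dtype="S1")[rng.integers(0, 4, size=length)]
               .tobytes().decode())
        genome[chrom] = seq
        models.append(
            TranscriptModel(
                transcript_id=chrom, gene_id=f"G{i:05d}", chrom=chrom, strand="+",
                exons=[(0, length)], cds_start=int(u5[i]),
                cds_end=int(u5[i] + cds[i]),
            )
        )
    return genome, models


# ----------------------------------------------------------------------
# methylome

_CONTEXT_LEFT = 4   # NSUN5 context reaches 4 nt upstream of the site
_CONTEXT_RIGHT = 6  # and 6 nt downstream
_MIN_SITE_SPACING = 12


def _write_context(seq: bytearray, pos: int, writer: str, rng: np.random.Generator) -> None:
    seq[pos] = ord("C")
    if writer == "NSUN2":
        # 3' G-rich context mimicking the tRNA variable loop
        for off in range(1, 6):
            if rng.random() < 0.9:
                seq[pos + off] = ord("G")
            else:
                seq[pos + off] = ord(rng.choice(list("ACT")))
    elif writer == "NSUN6":
        seq[pos: pos + 5] = b"CTCCA"
    elif writer == "NSUN5":
        template = "GTNGCCANNTG"  # site C is the fifth base (index 4)
        for k, ch in enumerate(template):
            p = pos - 4 + k
            seq[p] = ord(rng.choice(list("ACGT"))) if ch == "N" else ord(ch)
        seq[pos] = ord("C")


def simulate_methylome(
    genome: dict[str, str],
    transcripts: Sequence[TranscriptModel],
    config: SimConfig,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Place true m5C sites and rewrite their writer motifs into the genome.

    Returns the (modified) genome and a ground-truth table with one row per
    site (transcript, coordinate, strand, stoichiometry, writer label, and
    the 0..+5 motif as embedded).  Sites keep a minimum spacing so contexts
    cannot overwrite each other.
    """
    config.validate()
    rng = config.rng(2)
    mutable = {c: bytearray(s, "ascii") for c, s in genome.items()}
    lengths = np.array([m.length for m in transcripts], float)
    capacity = int(sum(max(0, (l - _CONTEXT_LEFT - _CONTEXT_RIGHT)) // _MIN_SITE_SPACING
                       for l in lengths))
    if config.n_true_sites > capacity:
        raise SimConfigError(
            f"requested {config.n_true_sites} sites but only ~{capacity} "
            "separable cytosine positions are available"
        )
    writers = list(config.writer_mix)
    probs = np.array([config.writer_mix[w] for w in writers])
    labels = rng.choice(writers, size=config.n_true_sites, p=probs)
    stoich = _draw_fractions(config.stoichiometry_distribution,
                             config.n_true_sites, rng)
    taken: dict[str, list[int]] = {m.chrom: [] for m in transcripts}
    rows = []
    weights = lengths / lengths.sum()
    for k in range(config.n_true_sites):
        for _attempt in range(1000):
            ti = int(rng.choice(len(transcripts), p=weights))
            m = transcripts[ti]
            lo, hi = _CONTEXT_LEFT, m.length - _CONTEXT_RIGHT
            if hi <= lo:
                continue
            pos = int(rng.integers(lo, hi))
            if all(abs(pos - q) >= _MIN_SITE_SPACING for q in taken[m.chrom]):
                break
        else:
            raise SimConfigError("could not place all sites; too dense")
        taken[m.chrom].append(pos)
        _write_context(mutable[m.chrom], pos, labels[k], rng)
        motif = mutable[m.chrom][pos: pos + 6].decode()
        rows.append(
            {
                "transcript_id": m.transcript_id, "chrom": m.chrom, "pos0": pos,
                "strand": "+", "tpos": pos, "stoichiometry": float(stoich[k]),
                "writer": labels[k], "motif": motif.replace("T", "U"),
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    truth = truth.sort_values(["chrom", "pos0"], kind="stable").reset_index(drop=True)
    return {c: s.decode() for c, s in mutable.items()}, truth


# ----------------------------------------------------------------------
# pileups

@dataclass
class ReplicatePileup:
    """Count-level evidence of one replicate plus its artifact read records."""

    counts: pd.DataFrame              # raw fields; post-3C primed equal to raw
    artifact_reads: list[ReadRecord]

    def with_3c(self) -> pd.DataFrame:
        from .counting import apply_3c

        return apply_3c(self.counts, self.artifact_reads)


def simulate_pileups(
    genome: dict[str, str],
    truth: pd.DataFrame,
    config: SimConfig,
) -> list[ReplicatePileup]:
    """Per-replicate per-cytosine conversion evidence.

    Coverage is drawn from the configured count distribution per cytosine;
    the non-converted count is Binomial(coverage, stoichiometry) at true
    sites and Binomial(coverage, conversion_failure_rate) elsewhere.  On top
    of this, a ``structured_read_fraction`` of reads is emitted as artifact
    read records, each covering five consecutive cytosines of which the
    first four are non-converted (>3, so the 3C filter rejects the read);
    their contributions are included in the raw counts.  Replicates are
    sampled independently.
    """
    config.validate()
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    for chrom in sorted(genome):
        arr = np.frombuffer(genome[chrom].encode(), dtype="S1")
        cpos = np.flatnonzero(arr == b"C")
        chroms.append(chrom)
        positions.append(cpos)
    sizes = np.array([p.size for p in positions])
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    all_chrom = np.concatenate(
        [np.repeat(c, s) for c, s in zip(chroms, sizes)]
    ) if len(chroms) else np.empty(0, dtype=object)
    all_pos = np.concatenate(positions) if positions else np.empty(0, int)
    n_cyt = all_pos.size

    p_true = np.full(n_cyt, config.conversion_failure_rate, float)
    chrom_index = {c: i for i, c in enumerate(chroms)}
    for _, site in truth.iterrows():
        ci = chrom_index[site["chrom"]]
        cpos = positions[ci]
        j = int(np.searchsorted(cpos, int(site["pos0"])))
        if j >= cpos.size or cpos[j] != int(site["pos0"]):
            raise SimConfigError(
                f"true site {site['chrom']}:{site['pos0']} is not a cytosine"
            )
        p_true[offsets[ci] + j] = site["stoichiometry"]

    out = []
    for rep in range(config.n_replicates):
        rng = config.rng(10 + rep)
        cov = _draw_counts(config.coverage_distribution, n_cyt, rng)
        nonconv = rng.binomial(cov, p_true)
        conv = cov - nonconv
        other = np.zeros(n_cyt, int)
        art_reads: list[ReadRecord] = []
        if config.structured_read_fraction > 0:
            add_non = np.zeros(n_cyt, int)
            add_conv = np.zeros(n_cyt, int)
            for ci, chrom in enumerate(chroms):
                lo, hi = offsets[ci], offsets[ci + 1]
                if hi - lo < 5:
                    continue
                total_reads = int(cov[lo:hi].sum())
                n_art = rng.binomial(total_reads, config.structured_read_fraction)
                starts = rng.integers(0, hi - lo - 4, size=n_art)
                for k, s in enumerate(starts):
                    rows = np.arange(lo + s, lo + s + 5)
                    nc_mask = np.array([True, True, True, True, False])
                    add_non[rows[nc_mask]] += 1
                    add_conv[rows[~nc_mask]] += 1
                    art_reads.append(
                        ReadRecord(
                            f"art_r{rep}_{chrom}_{k}", chrom, "+",
                            [(int(all_pos[r]), bool(m)) for r, m in zip(rows, nc_mask)],
                        )
                    )
            nonconv = nonconv + add_non
            conv = conv + add_conv
        counts = pd.DataFrame(
            {
                "chrom": all_chrom, "pos0": all_pos, "strand": "+",
                "nonconv_raw": nonconv, "conv_raw": conv, "other_raw": other,
                "nonconv_3c": nonconv, "conv_3c": conv, "other_3c": other,
            },
            columns=COUNT_COLUMNS,
        )
        out.append(ReplicatePileup(counts, art_reads))
    return out


# ----------------------------------------------------------------------
# depletion / overexpression conditions

def simulate_depletion(
    truth: pd.DataFrame,
    enzyme_label: str,
    residual_factor: float,
) -> pd.DataFrame:
    """Scale the stoichiometry of one writer's sites by ``residual_factor``.

    Knockout/knockdown uses a factor in [0, 1]; overexpression gain allows
    factors above 1 (stoichiometries are capped at 1).  Sites of other
    writers are untouched.
    """
    if enzyme_label not in WRITERS:
        raise ValueError(f"unknown enzyme label {enzyme_label!r}; expected one of {WRITERS}")
    if residual_factor < 0:
        raise ValueError("residual_factor must be non-negative")
    out = truth.copy()
    mask = out["writer"] == enzyme_label
    out.loc[mask, "stoichiometry"] = np.minimum(
        out.loc[mask, "stoichiometry"] * residual_factor, 1.0
    )
    return out


# ----------------------------------------------------------------------
# RBP footprints

@dataclass
class FootprintSim:
    """Two pseudo-replicate peak tables plus the intended centre positions."""

    rep1: pd.DataFrame
    rep2: pd.DataFrame
    centers: np.ndarray
    chroms: np.ndarray


def simulate_footprints(
    truth: pd.DataFrame,
    transcripts: Sequence[TranscriptModel],
    config: SimConfig,
    rbp: str = "RBP",
    enriched: bool = True,
    n_footprints: int = 200,
    offset_window: int = 50,
    rng: np.random.Generator | None = None,
) -> FootprintSim:
    """Place footprints for one RBP, optionally enriched near true sites.

    For an enriched RBP each footprint centre falls within ``offset_window``
    of a random true site with probability ``config.footprint_enrichment``
    (uniform over transcripts otherwise); a null RBP is always uniform.
    Two pseudo-replicates are emitted with jittered boundaries and sampled
    fold-enrichment / p-value columns, so peak filtering is exercised.
    """
    config.validate()
    if rng is None:
        rng = config.rng(20)
    tx_by_chrom = {m.chrom: m for m in transcripts}
    lengths = np.array([m.length for m in transcripts], float)
    weights = lengths / lengths.sum()
    centers = np.empty(n_footprints, int)
    chroms = np.empty(n_footprints, object)
    p_enr = config.footprint_enrichment if enriched else 0.0
    for k in range(n_footprints):
        if len(truth) and rng.random() < p_enr:
            site = truth.iloc[int(rng.integers(0, len(truth)))]
            chrom = site["chrom"]
            L = tx_by_chrom[chrom].length
            c = int(site["pos0"]) + int(rng.integers(-offset_window, offset_window + 1))
            c = int(np.clip(c, 0, L - 1))
        else:
            ti = int(rng.choice(len(transcripts), p=weights))
            chrom = transcripts[ti].chrom
            c = int(rng.integers(0, transcripts[ti].length))
        centers[k] = c
        chroms[k] = chrom

    def _replicate(rep_rng: np.random.Generator) -> pd.DataFrame:
        rows = []
        for k in range(n_footprints):
            L = tx_by_chrom[chroms[k]].length
            w = int(rep_rng.integers(30, 61))
            start = centers[k] - w // 2 + int(rep_rng.integers(-3, 4))
            end = start + w + int(rep_rng.integers(-3, 4))
            start, end = max(0, start), min(L, max(start + 10, end))
            fold = float(rep_rng.gamma(8.0, 1.0) + 1.0)
            p = float(10.0 ** (-rep_rng.uniform(2.0, 6.0)))
            rows.append(
                {"chrom": chroms[k], "start": start, "end": end,
                 "name": f"{rbp}_{k}", "score": int(min(1000, fold * 100)),
                 "strand": "+", "fold_enrichment": fold, "p_value": p}
            )
        return pd.DataFrame(rows)

    return FootprintSim(_replicate(rng), _replicate(rng), centers, chroms)
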