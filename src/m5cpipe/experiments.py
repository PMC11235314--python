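"""End-to-end simulation experiments validating the pipeline's guarantees.

Each function builds a synthetic study with :mod:`m5cpipe.simulate`, runs the
relevant analysis stage, and measures how well the ground truth is recovered.
These are the workflows behind the analysis drivers and the reproducibility
script; problem sizes are arguments so callers can trade precision for time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calling import CallThresholds, call_candidates, integrate_replicates
from .rbp import fdr_adjust, filter_footprints, window_enrichment
from .simulate import (
    SimConfig,
    simulate_footprints,
    simulate_methylome,
    simulate_pileups,
    simulate_transcriptome,
)
from .writers import build_pwm, scan_and_assign

__all__ = [
    "run_site_recovery",
    "run_noise_rejection",
    "run_writer_recovery",
    "run_null_calibration",
    "run_enrichment_ranking",
]


def _call_sites(genome, truth, cfg, thresholds=None):
    pileups = simulate_pileups(genome, truth, cfg)
    reps = [call_candidates(p.with_3c(), thresholds) for p in pileups]
    calls = integrate_replicates(reps, thresholds)
    return calls[calls.final_call] if len(calls) else calls


def run_site_recovery(
    seed: int = 1,
    n_transcripts: int = 1000,
    n_true_sites: int = 300,
) -> dict:
    """Recall/precision of the caller on noise-free evidence.

    Zero conversion failure and no artifact reads; deep constant coverage
    (1000x) keeps binomial fluctuation around the 10% ratio threshold
    negligible, so with stoichiometries >= 0.15 in two replicates every true
    site should be recovered and nothing else called.
    """
    cfg = SimConfig(
        seed=seed, n_transcripts=n_transcripts, n_true_sites=n_true_sites,
        conversion_failure_rate=0.0, structured_read_fraction=0.0,
        coverage_distribution=("constant", {"value": 1000}),
        stoichiometry_distribution=("uniform", {"low": 0.15, "high": 0.60}),
    )
    genome, models = simulate_transcriptome(cfg)
    genome, truth = simulate_methylome(genome, models, cfg)
    called = _call_sites(genome, truth, cfg)
    truth_keys = set(zip(truth.chrom, truth.pos0))
    called_keys = set(zip(called.chrom, called.pos0)) if len(called) else set()
    tp = len(truth_keys & called_keys)
    return {
        "recall": tp / len(truth_keys),
        "precision": tp / len(called_keys) if called_keys else float("nan"),
        "n_called": len(called_keys),
        "n_true": len(truth_keys),
    }


def run_noise_rejection(
    seeds=range(10),
    n_transcripts: int = 1000,
) -> dict:
    """False site calls on a methylation-free transcriptome.

    Background non-conversion at the 0.003 failure rate with over-dispersed
    coverage (NB mean 50); the joint requirement of >= 3 non-converted
    reads, >= 10% ratio and two-replicate support makes false calls
    vanishingly rare.
    """
    total = 0
    per_seed = []
    for seed in seeds:
        cfg = SimConfig(
            seed=int(seed), n_transcripts=n_transcripts, n_true_sites=0,
            conversion_failure_rate=0.003, structured_read_fraction=0.0,
        )
        genome, models = simulate_transcriptome(cfg)
        genome, truth = simulate_methylome(genome, models, cfg)
        called = _call_sites(genome, truth, cfg)
        per_seed.append(len(called))
        total += len(called)
    return {"false_calls_total": total, "per_seed": per_seed,
            "n_seeds": len(per_seed)}


def run_writer_recovery(
    seed: int = 1,
    n_train: int = 200,
    n_random: int = 1000,
    p_threshold: float = 1e-2,
) -> dict:
    """Held-out writer-label recovery of PWMs trained on synthetic motifs.

    Trains NSUN2 and NSUN6 PWMs on ``n_train`` embedded contexts each, then
    scans held-out motif-embedded sites and uniform-random 6-mers.
    """
    cfg = SimConfig(
        seed=seed, n_transcripts=160, n_true_sites=int(n_train * 3.2),
        writer_mix={"NSUN2": 0.5, "NSUN6": 0.5},
    )
    genome, models = simulate_transcriptome(cfg)
    genome, truth = simulate_methylome(genome, models, cfg)
    truth = truth.copy()
    truth["ctx"] = [genome[r.chrom][r.pos0: r.pos0 + 6] for r in truth.itertuples()]
    n2 = truth[truth.writer == "NSUN2"].ctx.tolist()
    n6 = truth[truth.writer == "NSUN6"].ctx.tolist()
    if min(len(n2), len(n6)) <= n_train:
        raise ValueError("not enough simulated sites to hold any out")
    pwms = {
        "NSUN2": build_pwm("NSUN2", n2[:n_train]),
        "NSUN6": build_pwm("NSUN6", n6[:n_train]),
    }
    held = [(c, "NSUN2") for c in n2[n_train:]] + [(c, "NSUN6") for c in n6[n_train:]]
    hits = [scan_and_assign(c, pwms, p_threshold=p_threshold) == lab for c, lab in held]
    rng = np.random.default_rng([seed, 91])
    rand = ["".join(rng.choice(list("ACGU"), 6)) for _ in range(n_random)]
    claimed = [scan_and_assign(c, pwms, p_threshold=p_threshold) != "other"
               for c in rand]
    return {
        "accuracy": float(np.mean(hits)),
        "n_heldout": len(held),
        "random_assignment_rate": float(np.mean(claimed)),
        "pwms": pwms,
    }


def _background_positions(genome, rng, keep: float = 0.25) -> pd.DataFrame:
    rows = []
    for chrom in sorted(genome):
        arr = np.frombuffer(genome[chrom].encode(), dtype="S1")
        cpos = np.flatnonzero(arr == b"C")
        cpos = cpos[rng.random(cpos.size) < keep]
        rows.append(pd.DataFrame({"chrom": chrom, "pos": cpos}))
    return pd.concat(rows, ignore_index=True)


def _site_frame(truth: pd.DataFrame) -> pd.DataFrame:
    return truth.rename(columns={"pos0": "pos"})[["chrom", "pos"]]


def run_null_calibration(
    seed: int = 1,
    n_rbps: int = 1000,
    n_transcripts: int = 60,
    n_true_sites: int = 300,
    n_footprints: int = 200,
) -> dict:
    """Fisher rejection rate when footprints are independent of sites.

    One simulated methylome is screened against ``n_rbps`` RBPs whose
    footprints are placed uniformly (no enrichment); the fraction of RBPs
    with p < 0.05 estimates the realised test size.
    """
    cfg = SimConfig(seed=seed, n_transcripts=n_transcripts,
                    n_true_sites=n_true_sites)
    genome, models = simulate_transcriptome(cfg)
    genome, truth = simulate_methylome(genome, models, cfg)
    rng = cfg.rng(77)
    background = _background_positions(genome, rng)
    sites = _site_frame(truth)
    pvals = []
    for _ in range(n_rbps):
        fp = simulate_footprints(truth, models, cfg, enriched=False,
                                 n_footprints=n_footprints, rng=rng)
        peaks = pd.DataFrame({"chrom": fp.chroms, "center": fp.centers})
        res = window_enrichment(sites, background, peaks, half_width=50)
        pvals.append(res.p_value)
    pvals = np.asarray(pvals)
    return {
        "rejection_rate": float(np.mean(pvals < 0.05)),
        "n_rbps": int(n_rbps),
        "p_values": pvals,
    }


def run_enrichment_ranking(
    seeds=range(100),
    n_null_rbps: int = 19,
    n_transcripts: int = 60,
    n_true_sites: int = 300,
    n_footprints: int = 200,
    footprint_enrichment: float = 0.8,
) -> dict:
    """How often the truly enriched RBP ranks first by BH q-value.

    Per seed, one RBP's footprints are placed near true sites with the
    configured enrichment and screened together with ``n_null_rbps``
    unenriched RBPs, exercising replicate intersection and peak filtering.
    """
    base = SimConfig(seed=20_000, n_transcripts=n_transcripts,
                     n_true_sites=n_true_sites,
                     footprint_enrichment=footprint_enrichment)
    genome, models = simulate_transcriptome(base)
    genome, truth = simulate_methylome(genome, models, base)
    background = _background_positions(genome, base.rng(78))
    sites = _site_frame(truth)
    wins = 0
    for seed in seeds:
        rng = np.random.default_rng([int(seed), 55])
        ps = []
        for k in range(1 + n_null_rbps):
            fp = simulate_footprints(truth, models, base, enriched=(k == 0),
                                     n_footprints=n_footprints, rng=rng)
            peaks = filter_footprints(fp.rep1, fp.rep2)
            if len(peaks) == 0:
                ps.append(1.0)
                continue
            res = window_enrichment(sites, background, peaks, half_width=50)
            ps.append(res.p_value if np.isfinite(res.p_value) else 1.0)
        qs = fdr_adjust(ps)
        if qs[0] <= qs[1:].min() and ps[0] < min(ps[1:]):
            wins += 1
    return {"top_rank_fraction": wins / len(list(seeds)), "n_seeds": len(list(seeds))}
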