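"""NSUN writer-enzyme assignment.

Three lines of evidence identify which NSUN methyltransferase deposited an
m5C site:

* **depletion contrasts** — a site is enzyme-dependent when its methylation
  level drops by more than 0.05 *and* falls below 0.10 upon knockout /
  knockdown of the enzyme (loss rule, NSUN2/NSUN6), or rises by at least
  0.05 to above 0.10 upon overexpression (gain rule, NSUN5);
* **sequence motifs** — position weight matrices over the six bases at
  offsets 0..+5 (the site C at offset 0), trained on dependence-called
  sites: NSUN2 targets carry a 3' G-rich context mimicking the tRNA
  variable loop, NSUN6 targets carry the CUCCA of tRNA 3' ends; arbitrary
  sites are then assigned by log-odds scanning with an exact match p-value;
* **corroboration** — base-pairing propensity meta-profiles around the
  sites, and per-site Pearson correlation of methylation level with enzyme
  expression across samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .structure import paired_mask

__all__ = [
    "classify_dependence_loss",
    "classify_dependence_gain",
    "WriterPWM",
    "build_pwm",
    "scan_and_assign",
    "write_meme",
    "read_meme",
    "pairing_propensity_profile",
    "methylation_expression_correlation",
]

BASES = "ACGU"
MOTIF_LENGTH = 6  # offsets 0..+5, site C at offset 0

# methylation levels are compared at printed (two-decimal) precision; the
# guard keeps knife-edge float arithmetic (0.14 - 0.09 vs 0.05) faithful
_EPS = 1e-9


# ----------------------------------------------------------------------
# dependence contrasts

def classify_dependence_loss(
    level_reference: float,
    level_depleted: float,
    coverage_reference: float | None = None,
    coverage_depleted: float | None = None,
    min_coverage: int = 20,
) -> str:
    """Loss rule for knockout/knockdown contrasts (NSUN2, NSUN6).

    Dependent iff the methylation ratio decreases by more than 0.05 and the
    residual level is below 0.10.  Returns 'uninformative' when either
    condition has coverage below 20 (if coverages are supplied).
    """
    if _uninformative(coverage_reference, coverage_depleted, min_coverage):
        return "uninformative"
    if (level_reference - level_depleted) > 0.05 + _EPS and level_depleted < 0.10 - _EPS:
        return "dependent"
    return "independent"


def classify_dependence_gain(
    level_control: float,
    level_overexpressed: float,
    coverage_control: float | None = None,
    coverage_overexpressed: float | None = None,
    min_coverage: int = 20,
) -> str:
    """Gain rule for overexpression contrasts (NSUN5).

    Dependent iff the level increases by at least 0.05 and exceeds 0.10 in
    the overexpression condition.
    """
    if _uninformative(coverage_control, coverage_overexpressed, min_coverage):
        return "uninformative"
    if (level_overexpressed - level_control) >= 0.05 - _EPS \
            and level_overexpressed > 0.10 + _EPS:
        return "dependent"
    return "independent"


def _uninformative(cov_a, cov_b, min_coverage) -> bool:
    for cov in (cov_a, cov_b):
        if cov is not None and cov < min_coverage:
            return True
    return False


def combine_verdicts(*verdicts: str) -> str:
    """Logical OR over dependence verdicts from independent depletion datasets."""
    informative = [v for v in verdicts if v != "uninformative"]
    if not informative:
        return "uninformative"
    return "dependent" if "dependent" in informative else "independent"


# ----------------------------------------------------------------------
# PWMs

def _normalise_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


@dataclass
class WriterPWM:
    """Position probability matrix (4 bases x 6 offsets) for one enzyme."""

    name: str
    matrix: np.ndarray                       # shape (4, 6), rows in BASES order
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.25
    n_training_sites: int = 0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.matrix.shape != (4, MOTIF_LENGTH):
            raise ValueError(f"PWM matrix must be 4x{MOTIF_LENGTH}")
        if not np.allclose(self.matrix.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        self._null = None  # lazy (scores, tail probabilities)

    # -- scoring -------------------------------------------------------
    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.matrix / self.background[:, None])

    def score(self, kmer: str) -> float:
        """Log2 likelihood ratio of the 6-mer vs the background model."""
        kmer = _normalise_rna(kmer)
        if len(kmer) != MOTIF_LENGTH:
            raise ValueError(f"need a {MOTIF_LENGTH}-mer, got {kmer!r}")
        lo = self.log_odds
        try:
            return float(sum(lo[BASES.index(b), i] for i, b in enumerate(kmer)))
        except ValueError:
            raise ValueError(f"non-ACGU base in {kmer!r}") from None

    def _null_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """Exact null score distribution over all 4^6 background 6-mers."""
        if self._null is None:
            lo = self.log_odds
            idx = np.indices((4,) * MOTIF_LENGTH).reshape(MOTIF_LENGTH, -1)
            scores = lo[idx, np.arange(MOTIF_LENGTH)[:, None]].sum(axis=0)
            probs = self.background[idx].prod(axis=0)
            order = np.argsort(scores)[::-1]
            scores, probs = scores[order], probs[order]
            self._null = (scores, np.cumsum(probs))
        return self._null

    def match_pvalue(self, score: float) -> float:
        """P(background 6-mer scores >= ``score``), exact by enumeration."""
        scores, tail = self._null_distribution()
        # scores are sorted descending; include ties at floating tolerance
        k = int(np.searchsorted(-scores, -score + 1e-9, side="right"))
        return float(tail[k - 1]) if k > 0 else 0.0


def build_pwm(
    name: str,
    sequences: Sequence[str],
    background: Sequence[float] | None = None,
    pseudocount: float = 0.25,
) -> WriterPWM:
    """Learn a PWM from the 0..+5 contexts of dependence-called sites.

    Column probabilities are ``(count + pseudocount) / (n + 4 pseudocount)``;
    DNA input is accepted (T is read as U).
    """
    if len(sequences) < 2:
        raise ValueError("need at least two training sequences")
    seqs = [_normalise_rna(s) for s in sequences]
    if any(len(s) != MOTIF_LENGTH for s in seqs):
        raise ValueError(f"all training sequences must have length {MOTIF_LENGTH}")
    counts = np.zeros((4, MOTIF_LENGTH))
    for s in seqs:
        for i, b in enumerate(s):
            if b not in BASES:
                raise ValueError(f"non-ACGU base in training sequence {s!r}")
            counts[BASES.index(b), i] += 1
    matrix = (counts + pseudocount) / (len(seqs) + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return WriterPWM(name, matrix, bg, pseudocount, len(seqs))


def scan_and_assign(
    context: str,
    pwms: Mapping[str, WriterPWM],
    p_threshold: float = 1e-2,
    details: bool = False,
):
    """Assign a site to an enzyme by anchored 6-mer PWM scanning.

    ``context`` is the sequence from the site C (offset 0) rightwards; it
    must cover offsets 0..+5 — a site within 5 nt of the transcript 3' end
    is 'uninformative'.  Each PWM's log-odds score on the anchored 6-mer is
    converted to an exact match p-value over the null distribution of
    background 6-mers; the best-scoring enzyme with p below the threshold
    wins, an exact score tie or no qualifying match yields 'other'.
    """
    if len(context) < MOTIF_LENGTH:
        label = "uninformative"
        return (label, {}) if details else label
    kmer = _normalise_rna(context[:MOTIF_LENGTH])
    results = {}
    for name, pwm in pwms.items():
        s = pwm.score(kmer)
        results[name] = (s, pwm.match_pvalue(s))
    qualifying = {n: s for n, (s, p) in results.items() if p < p_threshold}
    if not qualifying:
        label = "other"
    else:
        best = max(qualifying.values())
        winners = [n for n, s in qualifying.items() if s == best]
        label = winners[0] if len(winners) == 1 else "other"
    return (label, results) if details else label


# ----------------------------------------------------------------------
# MEME minimal motif format

def write_meme(pwms: Iterable[WriterPWM], path) -> None:
    pwms = list(pwms)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(BASES, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {MOTIF_LENGTH} "
                f"nsites= {pwm.n_training_sites} E= 0\n"
            )
            for col in pwm.matrix.T:
                fh.write(" " + " ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")


def read_meme(path) -> dict[str, WriterPWM]:
    pwms: dict[str, WriterPWM] = {}
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = iter(fh.read().splitlines())
    lines = list(lines)
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            toks = lines[i + 1].split()
            background = np.array([float(toks[k] ) for k in range(1, 8, 2)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            name = line.split()[1]
            i += 1
            header = lines[i].strip()
            nsites = 0
            for tok, nxt in zip(header.split(), header.split()[1:]):
                if tok == "nsites=":
                    nsites = int(nxt)
            cols = []
            i += 1
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                cols.append([float(x) for x in lines[i].split()])
                i += 1
            pwms[name] = WriterPWM(name, np.array(cols).T, background,
                                   n_training_sites=nsites)
            continue
        i += 1
    return pwms


# ----------------------------------------------------------------------
# corroboration profiles

def pairing_propensity_profile(
    sequences: Sequence[str],
    window: int = 50,
    engine: Callable[[str], np.ndarray] | None = None,
) -> tuple[np.ndarray, int, int]:
    """Fraction of sequences in which each offset is base-paired.

    ``sequences`` are windows of length ``2*window + 1`` centred on the site
    (or background cytosine).  Shorter sequences are excluded and counted.
    Returns ``(profile, n_used, n_excluded)``; profile index 0 is offset
    ``-window``.
    """
    if engine is None:
        engine = paired_mask
    width = 2 * window + 1
    used = 0
    excluded = 0
    acc = np.zeros(width)
    for seq in sequences:
        if len(seq) != width:
            excluded += 1
            continue
        acc += engine(seq)
        used += 1
    if used == 0:
        raise ValueError("no sequences of the required window length")
    return acc / used, used, excluded


def methylation_expression_correlation(
    levels: pd.DataFrame,
    coverage: pd.DataFrame,
    expression: pd.DataFrame,
    writer_labels: pd.Series,
    min_coverage: int = 20,
    min_samples: int = 5,
) -> pd.DataFrame:
    """Per-site Pearson r between methylation level and enzyme expression.

    ``levels`` and ``coverage`` are sites x samples; ``expression`` is
    enzymes x samples; ``writer_labels`` maps site -> predicted writer.  A
    site qualifies when its coverage exceeds ``min_coverage`` in at least
    ``min_samples`` samples; r is computed over exactly those samples.
    Zero-variance vectors yield a missing r, not an exception.
    """
    samples = levels.columns
    if not (coverage.columns.equals(samples) and expression.columns.equals(samples)):
        raise ValueError("levels, coverage and expression must share sample columns")
    rows = []
    cov = coverage.to_numpy(float)
    lev = levels.to_numpy(float)
    for i, site in enumerate(levels.index):
        ok = (cov[i] > min_coverage) & ~np.isnan(lev[i])
        if ok.sum() < min_samples:
            continue
        x = lev[i, ok]
        for enzyme in expression.index:
            y = expression.loc[enzyme].to_numpy(float)[ok]
            if np.std(x) == 0 or np.std(y) == 0:
                r = np.nan
            else:
                r = float(np.corrcoef(x, y)[0, 1])
            rows.append(
                {"site": site, "writer": writer_labels.get(site, "other"),
                 "enzyme": enzyme, "n_samples": int(ok.sum()), "r": r}
            )
    return pd.DataFrame(rows, columns=["site", "writer", "enzyme", "n_samples", "r"])
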