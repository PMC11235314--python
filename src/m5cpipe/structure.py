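"""Maximum base-pairing secondary structure (Nussinov) for propensity profiles.

The pairing propensity meta-profiles only need a coarse paired/unpaired call
per position, for which a maximum base-pairing fold is sufficient and fully
deterministic.  Watson-Crick pairs plus G:U wobble are allowed and hairpin
loops must contain at least ``min_loop`` unpaired bases.  The engine is
pluggable: any callable mapping a sequence to a boolean paired-mask can be
substituted (e.g. a thermodynamic folder).
"""

from __future__ import annotations

import numpy as np

__all__ = ["nussinov_pairs", "paired_mask"]

_CANONICAL = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in _CANONICAL


def nussinov_pairs(seq: str, min_loop: int = 3) -> list[tuple[int, int]]:
    """Base pairs of one maximum-pairing structure.

    Ties in the dynamic program are broken deterministically, preferring to
    close a pair (i, j) over leaving ends unpaired and taking the leftmost
    bifurcation point otherwise.
    """
    s = seq.upper().replace("T", "U")
    n = len(s)
    if n == 0:
        return []
    bases = np.frombuffer(s.encode(), dtype="S1")
    dp = np.zeros((n, n), dtype=np.int32)
    pairable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            pairable[i, j] = _can_pair(s[i], s[j])

    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = max(dp[i + 1, j], dp[i, j - 1])  # i or j unpaired
            if pairable[i, j]:
                best = max(best, dp[i + 1, j - 1] + 1)
            # bifurcation: split into [i, k] and [k+1, j]
            k = np.arange(i + min_loop + 1, j - min_loop - 1)
            if k.size:
                best = max(best, int((dp[i, k] + dp[k + 1, j]).max()))
            dp[i, j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i <= min_loop:
            continue
        if pairable[i, j] and dp[i, j] == dp[i + 1, j - 1] + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        if dp[i, j] == dp[i + 1, j]:
            stack.append((i + 1, j))
            continue
        if dp[i, j] == dp[i, j - 1]:
            stack.append((i, j - 1))
            continue
        done = False
        for k in range(i + min_loop + 1, j - min_loop - 1):
            if dp[i, j] == dp[i, k] + dp[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                done = True
                break
        if not done:  # numerical corner: fall back to skipping i
            stack.append((i + 1, j))
    return sorted(pairs)


def paired_mask(seq: str, min_loop: int = 3) -> np.ndarray:
    """Boolean array: True where the base is paired in the max-pairing fold."""
    mask = np.zeros(len(seq), dtype=bool)
    for i, j in nussinov_pairs(seq, min_loop=min_loop):
        mask[i] = mask[j] = True
    return mask
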