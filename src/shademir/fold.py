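"""Secondary-structure energy estimate for hairpin (pre-miRNA) candidates.

A Nussinov-style dynamic program over nested pairings with a minimum
hairpin loop of 3 nt, minimizing a per-pair energy (GC -3.0, AU -2.0,
GU -1.0 kcal/mol).  This is deliberately simpler than nearest-neighbor
thermodynamics: the absolute scale differs from full models, which is why
the hairpin energy threshold is a configurable parameter rather than a
universal constant.
"""

from __future__ import annotations

from .rnautil import pair_energy, to_rna

MIN_LOOP = 3


def fold_energy(sequence: str, min_loop: int = MIN_LOOP) -> float:
    """Minimum total energy (kcal/mol) over nested structures; <= 0."""
    return _fold(sequence, min_loop)[0]


def fold_structure(sequence: str, min_loop: int = MIN_LOOP):
    """(energy, pairs) where pairs is a dict of 0-based paired positions
    (both directions).  Traceback is deterministic: a position is left
    unpaired when that is co-optimal, and the smallest co-optimal pairing
    partner is chosen otherwise.
    """
    return _fold(sequence, min_loop)


def _fold(sequence: str, min_loop: int):
    seq = to_rna(sequence)
    n = len(seq)
    E = [[0.0] * n for _ in range(n)]
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = E[i][j - 1]  # j unpaired
            for k in range(i, j - min_loop):
                e = pair_energy(seq[k], seq[j])
                if e == 0.0:
                    continue
                left = E[i][k - 1] if k > i else 0.0
                inner = E[k + 1][j - 1] if k + 1 <= j - 1 else 0.0
                cand = left + e + inner
                if cand < best:
                    best = cand
            E[i][j] = best

    pairs: dict[int, int] = {}
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i <= min_loop:
            continue
        if E[i][j] == E[i][j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j - min_loop):
            e = pair_energy(seq[k], seq[j])
            if e == 0.0:
                continue
            left = E[i][k - 1] if k > i else 0.0
            inner = E[k + 1][j - 1] if k + 1 <= j - 1 else 0.0
            if left + e + inner == E[i][j]:
                pairs[k] = j
                pairs[j] = k
                if k > i:
                    stack.append((i, k - 1))
                if k + 1 <= j - 1:
                    stack.append((k + 1, j - 1))
                break
    return (E[0][n - 1] if n else 0.0), pairs
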