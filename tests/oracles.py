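"""Independent reference implementations used only as test oracles.

Each oracle restates its rule from scratch (naive counting, exhaustive
enumeration) and never calls the code path it checks.
"""

from __future__ import annotations

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
WOBBLE = {("G", "U"), ("U", "G")}


def naive_allen_recount(site_aligned: str, mir_aligned: str) -> float:
    """Column-by-column recount of the duplex penalty.

    First assigns a miRNA 5'-position to every column (mir chars numbered
    from the right-hand end of the 3'->5' string; a miRNA-side gap takes
    the position of the nearest miRNA base towards the 5' end), then sums
    penalties: WC 0, G:U 0.5, mismatch 1, gap 1, doubled at positions 2-13.
    """
    n = len(site_aligned)
    assert len(mir_aligned) == n
    positions = [0] * n
    p = 0
    for idx in range(n - 1, -1, -1):
        if mir_aligned[idx] != "-":
            p += 1
            positions[idx] = p
        else:
            positions[idx] = max(p, 1)
    total = 0.0
    for idx in range(n):
        s, m = site_aligned[idx], mir_aligned[idx]
        if s == "-" or m == "-":
            pen = 1.0
        elif (s, m) in WC:
            pen = 0.0
        elif (s, m) in WOBBLE:
            pen = 0.5
        else:
            pen = 1.0
        if 2 <= positions[idx] <= 13:
            pen *= 2.0
        total += pen
    return total


def brute_force_best_alignment(mirna: str, site: str) -> float:
    """Minimum duplex penalty over ALL global alignments, by exhaustive
    depth-first enumeration (no dynamic programming, no memoization).

    The miRNA is reversed so columns pair antiparallel; the penalty of each
    complete alignment is accumulated incrementally with the same counting
    rule as :func:`naive_allen_recount`.
    """
    r = mirna[::-1]
    L, S = len(r), len(site)

    def pen(s: str | None, m: str | None, mir_pos: int) -> float:
        if s is None or m is None:
            base = 1.0
        elif (s, m) in WC:
            base = 0.0
        elif (s, m) in WOBBLE:
            base = 0.5
        else:
            base = 1.0
        return base * (2.0 if 2 <= mir_pos <= 13 else 1.0)

    best = [float("inf")]

    def walk(i: int, j: int, acc: float) -> None:
        if i == S and j == L:
            if acc < best[0]:
                best[0] = acc
            return
        if j < L:
            mir_pos = L - j  # 5'-position of the miRNA char consumed next
            if i < S:
                walk(i + 1, j + 1, acc + pen(site[i], r[j], mir_pos))
            walk(i, j + 1, acc + pen(None, r[j], mir_pos))
        if i < S:
            mir_pos = max(L - j, 1)  # nearest miRNA base towards the 5' end
            walk(i + 1, j, acc + pen(site[i], None, mir_pos))

    walk(0, 0, 0.0)
    return best[0]


PAIR_E = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}


def enumerate_min_fold_energy(seq: str, min_loop: int = 3) -> float:
    """Minimum energy over every nested structure, by explicit recursion on
    the leftmost position (exhaustive, no tabulation)."""

    def rec(i: int, j: int) -> float:
        if j - i < min_loop + 1:
            return 0.0
        best = rec(i + 1, j)  # i unpaired
        for k in range(i + min_loop + 1, j + 1):
            e = PAIR_E.get((seq[i], seq[k]))
            if e is None:
                continue
            best = min(best, e + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(seq) - 1)


def categorize_by_printed_rules(tag5_counts: dict[int, int], position: int):
    """Straight-line restatement of the five degradome category rules."""
    c = tag5_counts.get(position, 0)
    if c == 0:
        return None
    if c == 1:
        return 4
    occupied = list(tag5_counts.values())
    maximum = max(occupied)
    average = sum(occupied) / len(occupied)
    if c == maximum and occupied.count(maximum) == 1:
        return 0
    if c == maximum:
        return 1
    if average < c < maximum:
        return 2
    return 3
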