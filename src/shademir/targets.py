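"""miRNA target-site scoring and transcriptome scanning.

The penalty scheme is the one used for plant miRNA/target duplexes
(Allen-style): Watson-Crick pair 0, G:U wobble 0.5, mismatch 1.0, gap 1.0,
with penalties doubled inside the 5' "core" of the miRNA (positions 2-13 by
default; position 1 is not doubled).  Positions are counted from the miRNA
5' nucleotide, and gaps on the miRNA side do not advance the position
counter.

Conventions
-----------
* ``site_aligned`` is the target-site strand written 5'->3'.
* ``mir_aligned`` is the miRNA written 3'->5', so the two strings pair
  column by column (antiparallel duplex).
* ``structure`` is a dot-bracket duplex string ``site&mir``: a column is
  ``(``/``)`` iff its two bases form a WC or G:U pair, ``.`` if not, ``-``
  for a gap.
* Transcript coordinates are 1-based inclusive, forward (mRNA) strand.
* The expected cleavage site is the transcript position opposite the 10th
  miRNA nucleotide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .rnautil import GAP, is_paired, pair_energy, to_rna

logger = logging.getLogger(__name__)

__all__ = [
    "AllenParams",
    "DuplexAlignment",
    "AlignmentError",
    "allen_score",
    "align_duplex",
    "duplex_energies",
    "extract_query",
    "scan_targets",
    "gapless_scores",
]


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class AllenParams:
    """Tunable weights of the duplex penalty scheme."""

    mismatch: float = 1.0
    wobble: float = 0.5
    gap: float = 1.0
    core_start: int = 2
    core_end: int = 13
    core_multiplier: float = 2.0

    def weight(self, mir_pos: int) -> float:
        if self.core_start <= mir_pos <= self.core_end:
            return self.core_multiplier
        return 1.0


DEFAULT_PARAMS = AllenParams()

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass
class DuplexAlignment:
    """An antiparallel miRNA:target-site alignment with its descriptors."""

    mirna_id: str
    transcript_id: str
    t_start: int
    t_stop: int
    site_aligned: str
    mir_aligned: str
    structure: str
    allen_score: float
    mfe_site: float
    mfe_perfect: float
    expected_cs: int

    @property
    def sequence(self) -> str:
        return f"{self.site_aligned}&{self.mir_aligned}"


def _column_cost(site_base: str, mir_base: str, params: AllenParams) -> float:
    if site_base == GAP or mir_base == GAP:
        return params.gap
    if is_paired(site_base, mir_base):
        if (site_base, mir_base) in (("G", "U"), ("U", "G")):
            return params.wobble
        return 0.0
    return params.mismatch


def allen_score(
    site_aligned: str,
    mir_aligned: str,
    params: AllenParams = DEFAULT_PARAMS,
) -> float:
    """Penalty of a gapped duplex, counted at miRNA positions.

    ``mir_aligned`` is 3'->5', so the miRNA position counter runs from the
    right-hand end of the string (position 1 = miRNA 5' nucleotide).
    """
    site_aligned = site_aligned.upper().replace("T", "U")
    mir_aligned = mir_aligned.upper().replace("T", "U")
    if len(site_aligned) != len(mir_aligned):
        raise AlignmentError(
            f"aligned strings differ in length "
            f"({len(site_aligned)} vs {len(mir_aligned)})"
        )
    total = 0.0
    pos = 0
    for s, m in zip(reversed(site_aligned), reversed(mir_aligned)):
        if s == GAP and m == GAP:
            raise AlignmentError("column with gaps on both strands")
        if m != GAP:
            pos += 1
            p = pos
        else:
            p = max(pos, 1)
        cost = _column_cost(s, m, params)
        if cost:
            total += cost * params.weight(p)
    return total


def _align_dp(mirna: str, site: str, params: AllenParams):
    """Global alignment of reversed miRNA vs site minimizing the penalty.

    Returns (score, site_aligned, mir_aligned).  DP value is the pair
    (score, gap columns) minimized lexicographically; remaining ties are
    broken in the traceback by preferring match, then site-side gap, then
    miRNA-side gap, which places gaps as far left as possible.
    """
    r = mirna[::-1]  # 3'->5'
    L, S = len(r), len(site)
    INF = (float("inf"), 0)

    # D[i][j]: site[:i] against r[:j]
    D = [[INF] * (L + 1) for _ in range(S + 1)]
    D[0][0] = (0.0, 0)
    for j in range(1, L + 1):
        w = params.weight(L - j + 1)
        prev = D[0][j - 1]
        D[0][j] = (prev[0] + params.gap * w, prev[1] + 1)
    for i in range(1, S + 1):
        wj0 = params.weight(max(L, 1))
        D[i][0] = (D[i - 1][0][0] + params.gap * wj0, D[i - 1][0][1] + 1)
        si = site[i - 1]
        for j in range(1, L + 1):
            w_mir = params.weight(L - j + 1)
            diag = D[i - 1][j - 1]
            cand = (diag[0] + _column_cost(si, r[j - 1], params) * w_mir, diag[1])
            up = D[i][j - 1]
            c_up = (up[0] + params.gap * w_mir, up[1] + 1)
            if c_up < cand:
                cand = c_up
            left = D[i - 1][j]
            w_gap = params.weight(max(L - j, 1))
            c_left = (left[0] + params.gap * w_gap, left[1] + 1)
            if c_left < cand:
                cand = c_left
            D[i][j] = cand

    # traceback
    i, j = S, L
    site_cols: list[str] = []
    mir_cols: list[str] = []
    while i > 0 or j > 0:
        cur = D[i][j]
        if i > 0 and j > 0:
            w_mir = params.weight(L - j + 1)
            diag = D[i - 1][j - 1]
            c = diag[0] + _column_cost(site[i - 1], r[j - 1], params) * w_mir
            if (c, diag[1]) == cur:
                site_cols.append(site[i - 1])
                mir_cols.append(r[j - 1])
                i, j = i - 1, j - 1
                continue
        if j > 0:
            w_mir = params.weight(L - j + 1)
            up = D[i][j - 1]
            if (up[0] + params.gap * w_mir, up[1] + 1) == cur:
                site_cols.append(GAP)
                mir_cols.append(r[j - 1])
                j -= 1
                continue
        site_cols.append(site[i - 1])
        mir_cols.append(GAP)
        i -= 1

    site_aligned = "".join(reversed(site_cols))
    mir_aligned = "".join(reversed(mir_cols))
    return D[S][L][0], site_aligned, mir_aligned


def _structure_string(site_aligned: str, mir_aligned: str) -> str:
    site_sym = []
    mir_sym = []
    for s, m in zip(site_aligned, mir_aligned):
        if s == GAP:
            site_sym.append(GAP)
            mir_sym.append(".")
        elif m == GAP:
            site_sym.append(".")
            mir_sym.append(GAP)
        elif is_paired(s, m):
            site_sym.append("(")
            mir_sym.append(")")
        else:
            site_sym.append(".")
            mir_sym.append(".")
    return "".join(site_sym) + "&" + "".join(mir_sym)


def _expected_cs_offset(site_aligned: str, mir_aligned: str, mir_pos: int = 10) -> int:
    """0-based offset (in site coordinates) of the miRNA position ``mir_pos``.

    If the column opposite that miRNA position is a site-side gap, the last
    consumed site position is used.
    """
    n_mir = sum(1 for c in mir_aligned if c != GAP)
    target = n_mir - mir_pos + 1  # rank of the mir char when read 3'->5' L..1
    consumed_mir = 0
    site_off = -1
    for s, m in zip(site_aligned, mir_aligned):
        if s != GAP:
            site_off += 1
        if m != GAP:
            consumed_mir += 1
            if consumed_mir == target:
                return max(site_off, 0)
    return max(site_off, 0)


def duplex_energies(alignment: DuplexAlignment) -> tuple[float, float]:
    """(mfe_site, mfe_perfect) under the simplified per-pair energy model.

    ``mfe_site`` sums pair energies over paired alignment columns;
    ``mfe_perfect`` is the energy of the miRNA paired perfectly (WC) along
    its full length.
    """
    mfe_site = 0.0
    for s, m in zip(alignment.site_aligned, alignment.mir_aligned):
        if s != GAP and m != GAP and is_paired(s, m):
            mfe_site += pair_energy(s, m)
    mfe_perfect = 0.0
    for m in alignment.mir_aligned:
        if m != GAP:
            mfe_perfect += -3.0 if m in "GC" else -2.0
    return mfe_site, mfe_perfect


def align_duplex(
    mirna: str,
    site: str,
    params: AllenParams = DEFAULT_PARAMS,
    *,
    mirna_id: str = "",
    transcript_id: str = "",
    t_start: int = 1,
    enforce_bounds: bool = True,
) -> DuplexAlignment:
    """Optimal antiparallel alignment of a miRNA against a candidate site.

    ``mirna`` and ``site`` are both given 5'->3'; the miRNA is reversed
    internally so columns pair antiparallel.
    """
    mirna = to_rna(mirna)
    site = to_rna(site)
    if enforce_bounds:
        if not 15 <= len(mirna) <= 26:
            raise AlignmentError(f"miRNA length {len(mirna)} outside 15-26")
        if abs(len(site) - len(mirna)) > 4:
            raise AlignmentError(
                f"site length {len(site)} outside miRNA length +/- 4"
            )
    score, site_aligned, mir_aligned = _align_dp(mirna, site, params)
    aln = DuplexAlignment(
        mirna_id=mirna_id,
        transcript_id=transcript_id,
        t_start=t_start,
        t_stop=t_start + len(site) - 1,
        site_aligned=site_aligned,
        mir_aligned=mir_aligned,
        structure=_structure_string(site_aligned, mir_aligned),
        allen_score=score,
        mfe_site=0.0,
        mfe_perfect=0.0,
        expected_cs=t_start + _expected_cs_offset(site_aligned, mir_aligned),
    )
    aln.mfe_site, aln.mfe_perfect = duplex_energies(aln)
    return aln


def extract_query(transcript: str, hit_pos: int, *, width: int = 26):
    """26-nt query window around a degradome 5'-end hit.

    The hit position occupies window position 14 (13 nt upstream, the
    position itself, then 12 nt downstream).  Returns ``(start, end, seq)``
    with 1-based inclusive coordinates, or ``None`` (logged) if the window
    would run off the transcript.
    """
    transcript = to_rna(transcript)
    if len(transcript) < width:
        raise AlignmentError(f"transcript shorter than {width} nt")
    start = hit_pos - 13
    end = hit_pos + (width - 14)
    if start < 1 or end > len(transcript):
        logger.debug("query window %d-%d out of bounds; site skipped", start, end)
        return None
    return start, end, transcript[start - 1 : end]


def _cost_matrix(params: AllenParams) -> np.ndarray:
    C = np.empty((4, 4))
    for a, ia in _CODE.items():
        for b, ib in _CODE.items():
            C[ia, ib] = _column_cost(a, b, params)
    return C


def _encode(seq: str) -> np.ndarray:
    lut = np.zeros(128, dtype=np.int8)
    for b, i in _CODE.items():
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def gapless_scores(
    mirna: str, transcript: str, params: AllenParams = DEFAULT_PARAMS
) -> np.ndarray:
    """Vector of gapless duplex penalties for every |miR|-nt window.

    Window at 0-based offset ``o`` covers transcript positions
    ``o+1 .. o+L`` and is scored against the reversed miRNA without gaps.
    Returns an empty array when the transcript is shorter than the miRNA.
    """
    mirna = to_rna(mirna)
    transcript = to_rna(transcript)
    L = len(mirna)
    if len(transcript) < L:
        return np.empty(0)
    C = _cost_matrix(params)
    r = _encode(mirna[::-1])
    t = _encode(transcript)
    # column j (0-based) pairs the miRNA nucleotide at 5'-position L - j
    w = np.array([params.weight(L - j) for j in range(L)])
    win = np.lib.stride_tricks.sliding_window_view(t, L)
    return (C[win, r[None, :]] * w[None, :]).sum(axis=1)


def scan_targets(
    mirna: str,
    transcriptome: Mapping[str, str] | Iterable[tuple[str, str]],
    score_threshold: float = 7.0,
    params: AllenParams = DEFAULT_PARAMS,
    *,
    mirna_id: str = "",
    refine_margin: float = 4.0,
    mfe_ratio_min: float | None = None,
) -> list[DuplexAlignment]:
    """Report every target site whose best duplex penalty is <= threshold.

    Windows are |miR| nt wide; a vectorized gapless pass screens offsets and
    the full gapped DP refines every window within ``refine_margin`` of the
    threshold.  Overlapping hits are collapsed to the best-scoring site
    (ties to the leftmost).  ``mfe_ratio_min``, if set, additionally
    requires mfe_site / mfe_perfect >= that ratio.
    """
    items = transcriptome.items() if isinstance(transcriptome, Mapping) else list(transcriptome)
    items = list(items)
    if not items:
        raise ValueError("empty transcriptome")
    mirna = to_rna(mirna)
    L = len(mirna)
    hits: list[DuplexAlignment] = []
    for tid, tseq in sorted(items):
        tseq = to_rna(tseq)
        scores = gapless_scores(mirna, tseq, params)
        if scores.size == 0:
            continue
        cand = np.flatnonzero(scores <= score_threshold + refine_margin)
        t_hits: list[DuplexAlignment] = []
        for o in cand:
            aln = align_duplex(
                mirna,
                tseq[o : o + L],
                params,
                mirna_id=mirna_id,
                transcript_id=tid,
                t_start=int(o) + 1,
                enforce_bounds=False,
            )
            if aln.allen_score > score_threshold:
                continue
            if mfe_ratio_min is not None and aln.mfe_perfect < 0:
                if aln.mfe_site / aln.mfe_perfect < mfe_ratio_min:
                    continue
            t_hits.append(aln)
        hits.extend(_collapse_overlaps(t_hits))
    return hits


def _collapse_overlaps(hits: Sequence[DuplexAlignment]) -> list[DuplexAlignment]:
    if not hits:
        return []
    hits = sorted(hits, key=lambda h: h.t_start)
    groups: list[list[DuplexAlignment]] = [[hits[0]]]
    for h in hits[1:]:
        if h.t_start <= groups[-1][-1].t_stop:
            groups[-1].append(h)
        else:
            groups.append([h])
    return [min(g, key=lambda h: (h.allen_score, h.t_start)) for g in groups]
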