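"""Small-RNA read cleaning, tag collapsing, composition statistics,
known-miRNA assignment and novel-hairpin evaluation.

Reads are cleaned per library: 3' adapter clipped, any read with a base
below the quality floor dropped, length-filtered to 17-25 nt, screened
against an optional ncRNA blacklist, transliterated to the RNA alphabet and
collapsed into unique tags with per-library counts.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .fold import fold_structure
from .rnautil import RNA_BASES, to_rna

__all__ = [
    "SequenceTag",
    "MirnaRecord",
    "HairpinReport",
    "CompositionReport",
    "FastqParseError",
    "clean_reads",
    "collapse_libraries",
    "composition_stats",
    "match_known",
    "evaluate_hairpin",
]

DEFAULT_LENGTH_BOUNDS = (17, 25)

# no reported plant miRNA carries these homopolymer runs
_HOMOPOLYMER = re.compile("A{7}|C{8}|G{6}|U{7}")


class FastqParseError(ValueError):
    pass


@dataclass
class SequenceTag:
    """A collapsed unique small-RNA sequence with per-library counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())


@dataclass
class MirnaRecord:
    id: str
    mature_sequence: str
    source: str = "known"  # "known" | "novel"
    family: str | None = None
    counts: dict[str, int] = field(default_factory=dict)


@dataclass
class HairpinReport:
    precursor: str
    mature_span: tuple[int, int]
    fold_energy: float
    max_mature_bulge: int
    has_two_nt_3p_overhang: bool
    homopolymer_violation: bool
    normalized_expression: float
    passes: bool


def _iter_fastq(reads):
    """Yield (index, sequence, phred list); name the record on parse errors."""
    if isinstance(reads, (str, bytes)) or hasattr(reads, "read"):
        it = SeqIO.parse(reads, "fastq")
    else:
        it = iter(reads)
    i = -1
    while True:
        i += 1
        try:
            rec = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise FastqParseError(f"malformed FASTQ record at index {i}: {exc}") from exc
        if hasattr(rec, "letter_annotations"):
            yield i, str(rec.seq), rec.letter_annotations.get("phred_quality", [])
        else:
            seq, qual = rec
            yield i, seq, list(qual)


def clean_reads(
    reads,
    adapter: str | None = None,
    min_quality: int = 30,
    length_bounds: tuple[int, int] = DEFAULT_LENGTH_BOUNDS,
    blacklist: Iterable[str] = (),
    library: str = "lib",
) -> list[SequenceTag]:
    """Clean one library of raw reads into collapsed unique tags.

    A read is dropped when any base of the post-trim sequence is below
    ``min_quality`` (interior trimming of a small RNA is ill-defined).
    Blacklist filtering is exact containment: a tag equal to, or fully
    contained in, a blacklist sequence is removed.
    """
    lo, hi = length_bounds
    counter: Counter[str] = Counter()
    adapter = adapter.upper() if adapter else None
    for _idx, seq, quals in _iter_fastq(reads):
        seq = seq.upper()
        if adapter:
            cut = seq.find(adapter)
            if cut >= 0:
                seq, quals = seq[:cut], quals[:cut]
        if not (lo <= len(seq) <= hi):
            continue
        if quals and min(quals[: len(seq)]) < min_quality:
            continue
        try:
            rna = to_rna(seq)
        except ValueError:
            continue  # ambiguous bases (N etc.) are unusable for tags
        counter[rna] += 1
    black = [to_rna(b) for b in blacklist]
    tags = [
        SequenceTag(s, {library: c})
        for s, c in counter.items()
        if not any(s in b for b in black)
    ]
    tags.sort(key=lambda t: t.sequence)
    return tags


def collapse_libraries(
    libraries: Mapping[str, object],
    **clean_kwargs,
) -> list[SequenceTag]:
    """Clean several libraries and merge their tags into one catalog."""
    merged: dict[str, SequenceTag] = {}
    lib_names = list(libraries)
    for lib, reads in libraries.items():
        for tag in clean_reads(reads, library=lib, **clean_kwargs):
            entry = merged.setdefault(tag.sequence, SequenceTag(tag.sequence, {}))
            entry.counts[lib] = entry.counts.get(lib, 0) + tag.counts[lib]
    tags = sorted(merged.values(), key=lambda t: t.sequence)
    for t in tags:
        for lib in lib_names:
            t.counts.setdefault(lib, 0)
    return tags


def tags_to_frame(tags: Sequence[SequenceTag]) -> pd.DataFrame:
    """TSV-ready tag table: sequence, length, one count column per library."""
    libs = sorted({lib for t in tags for lib in t.counts})
    rows = [
        {"sequence": t.sequence, "length": t.length,
         **{f"count_{lib}": t.counts.get(lib, 0) for lib in libs}}
        for t in tags
    ]
    return pd.DataFrame(rows, columns=["sequence", "length", *(f"count_{l}" for l in libs)])


@dataclass
class CompositionReport:
    length_percent: pd.Series
    first_nt_percent: pd.DataFrame
    base_percent: pd.Series


def composition_stats(tags: Sequence[SequenceTag], weighted: bool = True) -> CompositionReport:
    """Length histogram, first-nucleotide frequency by length and overall
    base percentages; all expressed as percentages.  An empty tag list
    yields empty (all-zero-length) structures rather than a division error.
    """
    if not tags:
        return CompositionReport(
            pd.Series(dtype=float),
            pd.DataFrame(columns=list(RNA_BASES), dtype=float),
            pd.Series(0.0, index=list(RNA_BASES)),
        )
    len_w: Counter[int] = Counter()
    first: dict[int, Counter[str]] = {}
    bases: Counter[str] = Counter()
    for t in tags:
        w = t.total_count if weighted else 1
        if w <= 0:
            continue
        len_w[t.length] += w
        first.setdefault(t.length, Counter())[t.sequence[0]] += w
        for b in t.sequence:
            bases[b] += w
    total = sum(len_w.values())
    length_percent = pd.Series(
        {L: 100.0 * c / total for L, c in sorted(len_w.items())}, dtype=float
    )
    fnt = pd.DataFrame(0.0, index=sorted(first), columns=list(RNA_BASES))
    for L, cnt in first.items():
        s = sum(cnt.values())
        for b, c in cnt.items():
            fnt.loc[L, b] = 100.0 * c / s
    base_total = sum(bases.values())
    base_percent = pd.Series(
        {b: 100.0 * bases.get(b, 0) / base_total for b in RNA_BASES}, dtype=float
    )
    return CompositionReport(length_percent, fnt, base_percent)


def _mismatches(tag: str, ref: str, max_len_diff: int = 2) -> int | None:
    """Ungapped 5'-anchored comparison; 3' overhang of up to ``max_len_diff``
    nt is trimmed/extended without penalty.  None = incomparable."""
    if abs(len(tag) - len(ref)) > max_len_diff:
        return None
    n = min(len(tag), len(ref))
    return sum(1 for a, b in zip(tag[:n], ref[:n]) if a != b)


def match_known(
    tags: Sequence[SequenceTag],
    reference: Sequence[MirnaRecord],
    max_mismatch: int = 2,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Assign each tag to at most one reference mature miRNA.

    Best assignment = fewest mismatches (ties broken lexicographically by
    reference id).  Returns (tag sequence -> reference id, per-miRNA count
    matrix with one row per reference id and one column per library).
    """
    ids = [r.id for r in reference]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate reference ids: {dupes}")
    ref_seqs = {r.id: to_rna(r.mature_sequence) for r in reference}
    libs = sorted({lib for t in tags for lib in t.counts})
    counts = pd.DataFrame(0, index=sorted(ids), columns=libs, dtype=int)
    assignments: dict[str, str] = {}
    for tag in tags:
        best: tuple[int, str] | None = None
        for rid in sorted(ids):
            mm = _mismatches(tag.sequence, ref_seqs[rid])
            if mm is None or mm > max_mismatch:
                continue
            if best is None or (mm, rid) < best:
                best = (mm, rid)
        if best is None:
            continue
        assignments[tag.sequence] = best[1]
        for lib, c in tag.counts.items():
            counts.loc[best[1], lib] += c
    return assignments, counts


def _longest_unpaired_run(pairs: dict[int, int], lo: int, hi: int) -> int:
    run = best = 0
    for i in range(lo, hi + 1):
        if i in pairs:
            run = 0
        else:
            run += 1
            best = max(best, run)
    return best


def evaluate_hairpin(
    precursor: str,
    mature_span: tuple[int, int],
    normalized_expression: float,
    energy_threshold: float = -18.0,
) -> HairpinReport:
    """Evaluate a candidate pre-miRNA against the hairpin criteria.

    ``mature_span`` is 1-based inclusive on the precursor.  The mature/star
    duplex implied by the minimum-energy structure is checked for the 2-nt
    3' overhang that Dicer recognizes: both mature ends must be paired and
    the star segment (the pairing partners shifted 2 nt 3'-ward) must fit
    inside the precursor without overlapping the mature.
    """
    precursor = to_rna(precursor)
    ms, me = mature_span
    if not (1 <= ms <= me <= len(precursor)):
        raise IndexError(f"mature_span {mature_span} outside precursor 1-{len(precursor)}")
    mature = precursor[ms - 1 : me]
    energy, pairs = fold_structure(precursor)
    bulge = _longest_unpaired_run(pairs, ms - 1, me - 1)
    homopoly = bool(_HOMOPOLYMER.search(mature))
    overhang = False
    p5 = pairs.get(ms - 1)
    p3 = pairs.get(me - 1)
    if p5 is not None and p3 is not None:
        star_lo = min(p5, p3) + 2
        star_hi = max(p5, p3) + 2
        inside = 0 <= star_lo and star_hi < len(precursor)
        overlaps = not (star_hi < ms - 1 or star_lo > me - 1)
        overhang = inside and not overlaps
    passes = (
        energy <= energy_threshold
        and bulge <= 4
        and not homopoly
        and normalized_expression > 10
    )
    return HairpinReport(
        precursor=precursor,
        mature_span=(ms, me),
        fold_energy=energy,
        max_mature_bulge=bulge,
        has_two_nt_3p_overhang=overhang,
        homopolymer_violation=homopoly,
        normalized_expression=normalized_expression,
        passes=passes,
    )
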