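"""Degradome (PARE) 5'-end profiles, cleavage categories and permutation
p-values.

A degradome tag marks the 5' end of an uncapped mRNA fragment; a pile-up of
tag 5' ends at the position opposite the 10th miRNA nucleotide is the
diagnostic signature of miRNA-guided cleavage.  Categories rank the
diagnostic position against the transcript's whole profile:

* 0 - count > 1, equal to the transcript maximum, unique maximum
* 1 - count > 1, equal to the maximum, >= 2 positions at the maximum
* 2 - count > 1, above the mean of occupied positions but below the maximum
* 3 - count > 1, at or below that mean
* 4 - exactly 1 read at the position

The mean is taken over occupied positions only (zeros excluded).  A count
of 1 is always category 4, even when it equals the transcript maximum.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .rnautil import to_rna
from .targets import (
    AllenParams,
    DEFAULT_PARAMS,
    DuplexAlignment,
    align_duplex,
    gapless_scores,
)

__all__ = [
    "DegradomeProfile",
    "CleavageHit",
    "build_profiles",
    "categorize",
    "coincidence_filter",
    "site_pvalue",
    "parse_tag_fasta",
]

_COUNT_SUFFIX = re.compile(r"_x(\d+)$")


@dataclass
class DegradomeProfile:
    """Per-transcript map of degradome tag 5'-end counts (1-based)."""

    transcript_id: str
    length: int
    tag5_counts: dict[int, int] = field(default_factory=dict)

    def count_at(self, position: int) -> int:
        return self.tag5_counts.get(position, 0)

    @property
    def total(self) -> int:
        return sum(self.tag5_counts.values())


@dataclass
class CleavageHit:
    alignment: DuplexAlignment
    observed_count: int
    category: int
    p_value: float = 1.0

    @property
    def transcript_id(self) -> str:
        return self.alignment.transcript_id

    @property
    def expected_cs(self) -> int:
        return self.alignment.expected_cs


def parse_tag_fasta(records: Iterable[tuple[str, str]]) -> list[tuple[str, int]]:
    """(sequence, count) pairs from (header, seq) records; a ``_xN`` header
    suffix encodes the tag count, absent = 1."""
    out = []
    for header, seq in records:
        m = _COUNT_SUFFIX.search(header.split()[0])
        out.append((to_rna(seq), int(m.group(1)) if m else 1))
    return out


def build_profiles(
    tags: Sequence[tuple[str, int]],
    transcriptome: Mapping[str, str],
    min_tag_len: int = 16,
) -> dict[str, DegradomeProfile]:
    """Map degradome tags onto transcripts by exact sense-strand substring
    match.  A multi-mapping tag increments the profile at every exact
    locus.  Tags shorter than ``min_tag_len`` are dropped.
    """
    if not transcriptome:
        raise ValueError("empty transcriptome")
    seqs = {tid: to_rna(s) for tid, s in transcriptome.items()}
    profiles = {
        tid: DegradomeProfile(tid, len(s)) for tid, s in seqs.items()
    }
    for tag, count in tags:
        tag = to_rna(tag)
        if len(tag) < min_tag_len:
            continue
        for tid, tseq in seqs.items():
            start = tseq.find(tag)
            while start >= 0:
                pos = start + 1
                prof = profiles[tid].tag5_counts
                prof[pos] = prof.get(pos, 0) + count
                start = tseq.find(tag, start + 1)
    return profiles


def categorize(profile: DegradomeProfile, position: int) -> int | None:
    """Degradome category 0-4 of a transcript position; None if no tag 5'
    end maps there."""
    if not 1 <= position <= profile.length:
        raise IndexError(
            f"position {position} outside transcript 1-{profile.length}"
        )
    c = profile.count_at(position)
    if c == 0:
        return None
    if c == 1:
        return 4
    counts = np.array(list(profile.tag5_counts.values()), dtype=float)
    maximum = counts.max()
    average = counts.mean()
    if c == maximum:
        return 0 if (counts == maximum).sum() == 1 else 1
    if c > average:
        return 2
    return 3


def coincidence_filter(
    alignment: DuplexAlignment, profile: DegradomeProfile
) -> CleavageHit | None:
    """Retain an alignment only when a degradome tag 5' end coincides with
    the expected cleavage position (the 10th nucleotide of
    complementarity)."""
    if alignment.transcript_id != profile.transcript_id:
        raise ValueError(
            f"transcript mismatch: alignment on {alignment.transcript_id!r}, "
            f"profile for {profile.transcript_id!r}"
        )
    count = profile.count_at(alignment.expected_cs)
    if count < 1:
        return None
    cat = categorize(profile, alignment.expected_cs)
    return CleavageHit(alignment, count, cat)


def _shuffle_finds_site(
    shuffled: str,
    transcript: str,
    profile: DegradomeProfile,
    max_score: float,
    max_category: int,
    params: AllenParams,
    refine_margin: float,
) -> bool:
    """True if the shuffled miRNA has any site on the transcript with
    penalty <= max_score whose expected cleavage position holds a tag pile
    of category <= max_category."""
    L = len(shuffled)
    scores = gapless_scores(shuffled, transcript, params)
    if scores.size == 0:
        return False
    for o in np.flatnonzero(scores <= max_score + refine_margin):
        aln = align_duplex(
            shuffled,
            transcript[o : o + L],
            params,
            transcript_id=profile.transcript_id,
            t_start=int(o) + 1,
            enforce_bounds=False,
        )
        if aln.allen_score > max_score:
            continue
        if profile.count_at(aln.expected_cs) < 1:
            continue
        if categorize(profile, aln.expected_cs) <= max_category:
            return True
    return False


def site_pvalue(
    hit: CleavageHit,
    profile: DegradomeProfile,
    mirna: str,
    transcript: str,
    n_shuffles: int = 100,
    seed: int = 0,
    params: AllenParams = DEFAULT_PARAMS,
    refine_margin: float = 4.0,
) -> float:
    """Composition-preserving miRNA-shuffle permutation p-value.

    Each shuffle rescans the transcript for any site at least as good as
    the observed hit (penalty <= observed, category <= observed);
    p = (k + 1) / (n_shuffles + 1).
    """
    mirna = to_rna(mirna)
    transcript = to_rna(transcript)
    rng = np.random.default_rng(seed)
    letters = np.array(list(mirna))
    k = 0
    for _ in range(n_shuffles):
        shuffled = "".join(rng.permutation(letters))
        if _shuffle_finds_site(
            shuffled, transcript, profile, hit.alignment.allen_score,
            hit.category, params, refine_margin,
        ):
            k += 1
    return (k + 1) / (n_shuffles + 1)
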