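# Methods

## Scope and data model

The package analyses miRNA-guided cleavage regulation between two light
conditions ("sun" and "shade", two replicates each). Five record types
carry the analysis: collapsed small-RNA tags with per-library counts
(`SequenceTag`), antiparallel miRNA:site alignments (`DuplexAlignment`),
per-transcript degradome 5'-end profiles (`DegradomeProfile`), regulation
calls (`RegulationCall`, `ExpressionRecord`) and joined regulatory pairs
(`RegulatoryPair`). All sequences are handled internally as uppercase RNA;
DNA input is transliterated (T→U) at ingest. Transcript coordinates are
1-based inclusive on the forward (mRNA) strand.

## Read cleaning and tag catalog

A read is kept when, after optional exact 3'-adapter clipping, every base
is at or above the Phred floor (default Q30) and the length is within
17–25 nt. Whole-read rejection is used rather than interior trimming:
trimming interior bases of a ~21-nt RNA changes its identity, which is the
quantity being counted. Reads containing ambiguous bases are dropped for
the same reason. Tags equal to or fully contained in a user-supplied
ncRNA blacklist sequence are removed (exact containment stands in for an
Rfam-style annotation screen). Collapsing conserves the total retained
read count by construction, and the suite asserts it.

Known-miRNA assignment is an ungapped, 5'-anchored comparison against a
mature reference with a mismatch budget (default 2) and a tolerated 3'
length difference of ≤ 2 nt (overhanging 3' bases are ignored). This
replaces a BLAST homology search: e-values depend on database size,
whereas a fixed mismatch budget is deterministic and auditable at desk
scale. Ties go to the lexicographically smallest reference id.

## Duplex penalty and alignment

The plant-style penalty scheme: per aligned column, Watson–Crick 0, G:U
wobble 0.5, mismatch 1.0, gap 1.0; the penalty is doubled when the column
sits at miRNA positions 2–13 counted from the miRNA 5' end (position 1 is
not doubled; miRNA-side gaps do not advance the position counter). All
weights, and the doubling window itself, are parameters of `AllenParams`,
because published shortlist scores are internally consistent with this
scheme for some rows (the miR414 row reproduces exactly at 4.5) but
differ by 0.5 on others where the printed strand orientation is
ambiguous.

`align_duplex` is a global dynamic program over (site, reversed miRNA)
minimizing the penalty; the DP value is the pair (penalty, gap columns)
compared lexicographically, so among equal-penalty alignments one with
fewer gaps wins; remaining ties are resolved by a fixed traceback
preference (match, then site-side gap, then miRNA-side gap). The suite
checks the DP against exhaustive enumeration of all global alignments on
short cases. For the printed miR399b/OsPP2C duplex the DP returns the
same penalty (8.5) and gap budget (one site-side gap) as the printed
alignment, with a co-optimal gap placement.

`scan_targets` slides a |miR|-nt window along each transcript. A
vectorized gapless scorer screens every offset; windows within
`refine_margin` (default 4.0 penalty units) of the threshold are refined
with the full gapped DP. The margin bounds how much an internal bulge
could improve on the gapless register within one window; sites whose
gapped optimum beats their gapless score by more than the margin at every
overlapping offset would be missed, a trade accepted for a ~50× speedup.
Overlapping hits collapse to the best-scoring site (ties to the
leftmost). The reporting threshold defaults to 7.0 penalty units, the
conventional cutoff for this scheme; an optional
mfe_site/mfe_perfect-ratio filter exists but is off by default.

Duplex energies use a simplified per-pair model (GC −3, AU −2, GU −1
kcal/mol): `mfe_site` sums paired columns, `mfe_perfect` assumes full
Watson–Crick pairing of the miRNA. These are descriptors for ranking and
display, not thermodynamic predictions; printed free energies from
nearest-neighbour models are carried as provenance only.

## Degradome validation

Degradome tags (≥ 16 nt) are matched to transcripts by exact sense-strand
substring search; a multi-mapping tag increments every locus it matches
(CleaveLand-like behaviour; the alternative of fractional weights is a
flag on the roadmap but not default). The expected cleavage site of an
alignment is the transcript position opposite miRNA nucleotide 10; an
alignment survives only if at least one tag 5' end maps exactly there.

Categories follow the five printed rules 0–4 with the occupied-position
average (zeros excluded) and with a count of 1 always category 4, even
when it is the transcript maximum. An independent straight-line
re-statement of the rules is kept in the test suite as the oracle.

The degradome p-value is this package's own construction (the upstream
literature prints p-values without defining them): a
composition-preserving shuffle of the miRNA is rescanned against the
transcript `n_shuffles` times (default 100); a shuffle succeeds if it
finds any site with penalty ≤ the observed hit's penalty whose expected
cleavage position holds a tag pile of category ≤ the observed category;
p = (k+1)/(n+1), so p ∈ (0, 1] and the floor at 100 shuffles is ≈ 0.0099.
Calibration is tested by drawing random miRNA/transcript/profile triples,
selecting the observed hit under the same occupancy constraint the
shuffles face, and checking that p ≤ 0.05 occurs in ≤ 7% of trials.

## Expression classification

Size factors are median-of-ratios: for every feature with a positive
geometric mean across libraries, the ratio count/geomean is formed, and a
library's factor is the median of its ratios. miRNA log₂FC is
shade-over-sun on normalized means with a pseudocount of 1.0 (prevents
infinite fold changes; unique-expression calls are made on raw zeros, so
the pseudocount never masks them). The significance filter is a
two-sided Poisson-ratio test (conditional binomial on rounded normalized
sums). With two replicates per condition a dispersion estimate is not
supportable, and the pipeline's own filter (p ≤ 0.9) is so permissive
that the choice of test barely affects membership; the test is pluggable.
Because the test statistic uses rounded normalized sums, class labels are
exactly invariant under library rescaling except through rounding of a
global scale factor — the seeded invariance tests never observe a flip.

Boundaries are inclusive: |log₂FC| = 1.0 counts as up/down for miRNAs,
|log₂FC| = 0.25 for targets. `unique_*` requires all raw counts zero in
the other condition and a normalized mean ≥ 5 (the catalog's own
copy-number floor). Whether the novel-miRNA expression floor (> 10) is
per-library or summed is unspecified upstream; it is applied to the
summed normalized expression, and the parameter is exposed.

## Hairpin filter

`evaluate_hairpin` folds the precursor with a Nussinov-style DP
(per-pair energies as above, hairpin loop ≥ 3 nt) and reports: fold
energy (threshold −18 kcal/mol, configurable — the absolute scale of a
simplified model is not comparable across models); the longest unpaired
run within the mature region (≤ 4 to pass); homopolymer violations
(A₇/C₈/G₆/U₇ anywhere in the mature); and the 2-nt 3' overhang of the
implied mature/star duplex. The star is taken as the pairing partners of
the mature ends shifted 2 nt 3'-ward; the overhang flag requires both
mature ends paired and the star to fit inside the precursor without
overlapping the mature. The overhang is reported but not part of the
pass/fail invariant. Traceback ties prefer leaving a base unpaired, then
the smallest pairing partner — deterministic, which is what the
downstream bulge measurement needs.

## Integration

A pair enters the shortlist only with degradome evidence (category 0–4)
and a contrasting class combination: miR up × target down, miR down ×
target up, unique_shade × down, unique_sun × up, or neutral × (up|down)
(the differential-binding hypothesis). Same-direction and neutral×neutral
combinations are retained in the full pair table as `discordant` but
excluded from the shortlist. The published table's colour coding becomes
an explicit `mir_regulation` column. Gene names and functions come from a
user-supplied annotation mapping; there are no remote lookups. Pathway
tallies are simple percentage distributions (summing to 100 within each
split) over a user-supplied target→pathway map.

## Synthetic data

The generator emulates the study design at desk scale: default 8 miRNAs
(20–22 nt) × 12 transcripts (400–700 nt), 2 conditions × 2 replicates.
Small-RNA counts are negative-binomial (size 10) around a per-library
mean of `depth` (default 200) × 2^(±log₂FC/2); planted |log₂FC| is 2.0,
and uniquely expressed miRNAs are emitted in one condition only. These
defaults make the count signal unambiguous relative to NB noise, which is
the intended regime for validating the pipeline's logic (class
boundaries, joins, filters) rather than its power at marginal depth.
Planted sites are reverse complements mutated to an exact designed
penalty (defaults 0–3, cycled), re-verified through the aligner at
generation time. Degradome tags give the diagnostic position a planted
peak of `peak_fraction` (default 0.9) of the site's 40-tag budget;
remaining site tags and a uniform background (0.02 tags/nt) fall on
non-diagnostic positions, so the diagnostic share equals `peak_fraction`
exactly and a `peak_fraction` of 0 leaves the coincidence filter nothing
to find. Target log₂FC values are the planted class magnitudes (±1.0)
plus N(0, 0.05) noise; decoy transcripts get N(0, 0.1).

What the generator does **not** emulate: sequencing error, adapter
chemistry, rRNA contamination, 3'-biased degradome background (a flagged
option, default off), multi-site targets, isomiR heterogeneity, and
genome-scale transcriptome size. Passing recovery tests therefore
demonstrate correctness of the analysis logic under the stated
statistical structure, not performance on real libraries.

`recover` runs the full pipeline on a bundle and reports shortlist
sensitivity against the planted truth plus false pairs (with a strict
count at category 0 and p ≤ 0.05). Across seeds 1–10 at the defaults the
aggregate sensitivity is 1.0 with zero false pairs.

## Determinism and seeds

All randomness flows from integer seeds through `numpy`'s PCG64
generator. Bundles are byte-identical across runs for a fixed seed.
Per-hit permutation seeds are derived from the master seed and the
(miRNA, transcript) labels via CRC32, keeping p-values independent of
iteration order and below 2³¹.

## Problem sizes used in the checks

Alignment-DP oracle: 300 random cases at |miR| 4–7 (site |miR| ± 2),
where exhaustive enumeration of all global alignments is tractable;
fold-DP oracle: 200 random sequences of length 10–14; categorizer oracle:
1000 random profiles; recovery: seeds 1–10 at generator defaults; null
calibration: 200 trials at 60 shuffles. These sizes were chosen as the
smallest at which the checks are decisive.

## Known limitations

* The degradome-driven 26-nt query mode (`extract_query`) registers the
  hit position at window position 14 (13 nt upstream, 12 nt downstream);
  the symmetric "13 and 13" phrasing found in the literature would give a
  27-nt window, so one side must lose a base and the downstream side was
  chosen, fixed for determinism.
* The gapless pre-screen margin makes `scan_targets` heuristic for
  heavily bulged sites (see above).
* The permutation p-value is a reinterpretation; published degradome
  p-values were produced by an undefined procedure and are not
  comparable number-for-number.
* Median-of-ratios factors degrade when very few features are expressed
  in all libraries; the generator always plants neutral species, and real
  catalogs are far denser.
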