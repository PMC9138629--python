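# shademir

Integrated miRNA-regulation analysis for prolonged shade in rice: small-RNA
tag processing, plant-style miRNA target prediction, degradome (PARE)
cleavage validation, and the integration of miRNA regulation with target
expression into a shortlist of candidate regulatory pairs.

## Who this is for

Plant small-RNA researchers who have (i) two-condition small-RNA libraries,
(ii) degradome 5'-tag libraries on the same material, and (iii) a
transcript-level expression table (microarray or RNA-seq log₂FC), and who
want the classical three-way evidence chain for miRNA-guided cleavage:

1. the miRNA is expressed and classifiable (up / down / neutral / unique
   to one condition),
2. a complementary target site exists and a degradome tag pile-up sits
   exactly opposite the 10th nucleotide of complementarity,
3. the target's expression moves opposite to the miRNA (or, for neutral
   and uniquely expressed miRNAs, moves at all — the differential-binding
   hypothesis).

A synthetic-data generator with planted ground truth makes every stage
testable without any sequencing download.

## The statistics at the core

**Duplex penalty (Allen scheme).** A miRNA:site duplex, written
antiparallel, is scored per column: Watson–Crick pair 0, G:U wobble 0.5,
mismatch 1, gap 1, with penalties **doubled at miRNA positions 2–13**
(position 1 is not doubled). Alignment is a global dynamic program
minimizing this penalty; sites scoring ≤ 7.0 (configurable) are candidate
targets. For the published miR414 / *Os06t0561200-01* duplex this scorer
returns **4.5**, matching the printed value.

**Cleavage site and degradome categories.** The expected cleavage site
(CS) is the transcript position opposite miRNA nucleotide 10. A candidate
is validated only if at least one degradome tag 5' end maps exactly there;
the pile-up is ranked against the transcript's whole tag profile into
categories 0–4 (0 = unique transcript maximum, 1 = tied maximum,
2 = above the mean of occupied positions, 3 = at/below that mean,
4 = a single read). A composition-preserving miRNA-shuffle permutation
test attaches an empirical p-value, p = (k+1)/(n+1).

**Regulation classes.** Counts are normalized by median-of-ratios size
factors; miRNAs are classed up/down at |log₂FC| ≥ 1 (p ≤ 0.9, a
deliberately permissive filter), unique_sun/unique_shade on raw zeros in
the other condition, neutral otherwise. Targets are classed at
|log₂FC| ≥ 0.25. qPCR fold changes use 2^(−ΔΔCt).

**Hairpin (novel miRNA) filter.** Precursor candidates must fold to
≤ −18 kcal/mol (simplified per-pair energy model: GC −3, AU −2, GU −1,
loop ≥ 3), show a mature-region bulge ≤ 4 nt, a 2-nt 3' overhang in the
mature/star duplex, no A₇/C₈/G₆/U₇ homopolymer run, and normalized
expression > 10.

## Worked example

```python
from shademir import SimulationConfig, generate, recover

bundle = generate(SimulationConfig(seed=1))   # 8 miRNAs, 12 transcripts
report = recover(bundle)                      # full pipeline vs. truth
print(report.shortlist[["mirna", "target_id", "cleavage_site", "category",
                        "allen_score", "p_value", "mir_regulation"]].to_string(index=False))
print(f"sensitivity={report.sensitivity:.2f}  false_pairs={len(report.false_pairs)}")
```

prints

```
 mirna target_id  cleavage_site  category  allen_score  p_value mir_regulation
mir001     TX001            149         0          0.0 0.009901             up
mir002     TX002            442         0          1.0 0.009901           down
mir003     TX003            301         0          2.0 0.009901        neutral
mir004     TX004            423         0          3.0 0.009901   unique_shade
mir005     TX005            254         0          0.0 0.009901     unique_sun
mir006     TX006             88         0          1.0 0.009901             up
mir007     TX007            149         0          2.0 0.009901           down
mir008     TX008             76         0          3.0 0.009901        neutral
sensitivity=1.00  false_pairs=0
```

Every planted site is recovered at category 0 (the diagnostic tag is the
unique transcript maximum), with the permutation p-value at its floor of
1/101, and each pair lands in the regulation class the generator planted
(including the shade-unique silencing and differential-binding cases).

The same run is available from the shell:

```bash
shademir simulate --seed 1 --out bundle/
shademir run bundle/ --out results/ --seed 1
shademir report bundle/
```

Other subcommands (`clean`, `catalog`, `de`, `scan`, `degradome`,
`integrate`) expose the individual stages on FASTQ/FASTA/TSV files.

## Reference shortlist

`shademir.integrate.load_reference_shortlist()` returns the packaged
transcription of the published 16-miRNA / 21-pair shortlist (alignment
ranges, cleavage sites, categories, Allen scores, duplex strings); tests
assert its internal consistency (every cleavage site inside its alignment
range).

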