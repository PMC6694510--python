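# f2mosaic

Founder-mosaic genotype reconstruction for F2 intercrosses bred from
**outbred** founders of two divergent lines, using high-coverage founder
sequencing and very low-coverage (< 0.5×) skim sequencing of the offspring.

## The problem

Experimental F2 intercrosses are a workhorse for QTL mapping, but genotyping
hundreds of offspring densely is expensive. When the two founder lines are
outbred, the F0 linkage phases are unknown, so line origin cannot be read off
everywhere in the genome. The key observation this package implements: within
each *nuclear family* (one F2, its two F1 parents, its four line-labelled F0
grandparents), markers where the two H-line founders are homozygous for one
allele and the two L-line founders are homozygous for the other are **fully
informative for line origin** — every offspring read at such a marker reveals
which line the sequenced chromosome came from, so sub-1× coverage suffices.

The pipeline:

1. **select** — filter founder variants (MAF > 0.043, AC > 5, QUAL > 30) and
   pick, per family, the markers fixed for alternative alleles between the
   founder line pairs (a pooled per-line mode with a frequency slack δ is
   also provided).
2. **impute** — polarize offspring ref/alt allele depths into line counts
   (n_H, n_L); drop individuals with fewer than 5 read-covered markers per
   Mb; decode each chromosome with a chromosome-specific three-state HMM
   (hidden states HH/HL/LL; the six-state observation alphabet
   HH/HU/HL/LL/LU/UU expresses per-site read ambiguity). Emissions are
   per-site binomials — each read supports H with probability 1−ε′ (HH),
   0.5+b (HL) or ε′ (LL), with ε′ and the allele-ratio bias b estimated from
   sliding windows of 200 (large chromosomes) or 50 (small) consecutive
   markers. Transitions between adjacent markers use Haldane's map function
   r = ½(1 − e^(−2d)) on the physical gap at a configurable cM/Mb rate.
3. **QC / export** — remove double-recombination segments shorter than 3 Mb
   (crossover interference makes them implausible), drop individuals whose
   call rate then falls below 90% (or that are crossover-count outliers),
   summarize mosaics into 1-Mb bins and export R/qtl CSV genotypes
   (A/H/B/−). Each inferred crossover carries a breakpoint interval: the gap
   between the flanking read-covered informative markers.
4. **simulate / evaluate** — a full-truth generator (two-line founders,
   meioses with hard 5-Mb crossover interference, Poisson skim reads with
   per-read error) and agreement metrics per individual and per marker.

## Worked example

Simulate a small two-family cohort (30-Mb genome), select markers, and
impute:

```bash
f2mosaic simulate --out sim --seed 5 --n-families 2 --chrom-mb 20,10
f2mosaic select sim/founders.vcf sim/pedigree.tsv --out markers
f2mosaic impute sim/offspring.vcf markers sim/pedigree.tsv sim/genome.tsv --out impute
```

The select step logs the founder filter and per-family marker counts:

```
INFO founder filter: {'input': 224376, 'removed_all_missing': 0, 'removed_maf': 5529,
                      'removed_ac': 56612, 'removed_qual': 0, 'retained': 164991}
INFO family fam0_F2: 23454 informative markers
INFO family fam1_F2: 23321 informative markers
INFO imputation: kept 2, density-dropped 0, outlier-dropped 0
```

i.e. ~780 informative markers/Mb per family. `impute/` then contains the
segment table (`segments.tsv`, one HH/HL/LL/UU segment per row with
breakpoint flanks), the QC report, R/qtl genotypes, and the
breakpoint-resolution summary:

```json
{"n": 2, "median": 7254.5, "q25": 4526.75, "q75": 9982.25, "mean": 7254.5}
```

meaning both inferred crossovers in this toy cohort were localized to
~4.5–10 kb intervals at 0.33× coverage. The QC report
(`qc_report.tsv`) lists call rate and genome-wide crossover count per
individual:

```
individual  call_rate  crossovers  flagged
fam0_F2     1.0        1           False
fam1_F2     1.0        1           False
```

The same stages are available as library functions
(`f2mosaic.run_select`, `f2mosaic.impute_cohort`,
`f2mosaic.simulate_dataset`, `f2mosaic.truth_agreement`, …) for in-memory
use.

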