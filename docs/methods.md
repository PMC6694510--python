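# Methods

## Setting and model

An F2 intercross from two divergent but outbred (heterozygous) founder
lines, H and L, is analysed one nuclear family at a time: one F2 offspring,
its two F1 parents and its four F0 grandparents (two per line). Because F0
linkage phases are unknown, inference is restricted to *within-family
informative markers* — biallelic SNPs where both H founders are homozygous
for one allele and both L founders homozygous for the other. At such a
marker every F1 is heterozygous (so F1s need not be sequenced) and every
offspring read identifies the line of origin of the sequenced homologue.
Offspring read depths are polarized into counts (n_H, n_L) of reads
supporting the H and L alleles.

The line-origin genotype along each chromosome is modelled as a
three-state hidden Markov chain with states {HH, HL, LL}:

- **Initial distribution** (0.25, 0.5, 0.25), the Mendelian F2 prior.
- **Transitions.** For adjacent markers separated by d bp, the per-gamete
  recombination fraction is Haldane's r = ½(1 − exp(−2·d·ρ)), with ρ the
  configured map rate (default 3.0 cM/Mb, approximately the chicken
  genome-wide average; configurable because the pipeline is genome-
  agnostic). Single-crossover moves HH↔HL and HL↔LL have probability r, the
  double-crossover move HH↔LL has r², and self-transitions take the
  remaining mass. This is a deliberate simplification of the exact F2
  two-gamete kernel (which would use 2r(1−r) and r² with matched
  normalization); for the sub-centimorgan gaps between informative markers
  the two agree to first order in r.
- **Emissions.** At a marker with n = n_H + n_L reads, n_H is Binomial(n,
  p_s) with per-read H probability p_s of 1−ε′ (HH), 0.5+b (HL), ε′ (LL).
  ε is the per-read line-flip error (default 0.01, deliberately above the
  simulator's generative 0.005 to absorb mapping artefacts). Markers with
  no reads emit probability 1 under all states, so uncovered stretches are
  bridged by the transition model alone.
- **Chromosome-specific parameters.** Read totals are aggregated in
  non-overlapping windows of 200 consecutive markers on large chromosomes
  and 50 on small ones (a chromosome is "small" when it carries fewer than
  2,000 informative markers — the size split is a documented convention of
  the window scheme and the threshold is configurable, since no published
  cutoff exists). Windows whose H-read fraction f lies in [0.25, 0.75] are
  treated as sampling heterozygous regions; the allele-ratio bias
  b = median(f) − 0.5 (clipped to ±0.2) is folded into the emissions as a
  uniform log-odds shift that places the HL state exactly at 0.5+b and
  moves the homozygous states' ε accordingly (ε′). With unbiased data
  b ≈ 0 and ε′ = ε. Windows also flag zero-read stretches for diagnostics.

Decoding is Viterbi by default (joint most probable path; ties broken
toward the previous marker's state, which favors fewer crossovers), with a
max-posterior alternative. Runs of identical states become segments. Each
boundary carries a **breakpoint interval**: the span between the last
read-covered marker before the switch and the first after it; the segment
boundary is placed at the interval midpoint (unbiased under a uniform
position prior) and chromosome ends are extended to [1, length]. The
observation-level six-state alphabet (HH, HU, HL, LL, LU, UU; U = unknown)
is implemented as a per-site classification — HU/LU mean "one line
observed but below the homozygote read threshold k (default 2)", UU means
no reads — and is exposed for diagnostics; the hidden state space stays
three-valued because final genotypes are three-valued.

## Quality control

- **Density filter.** Individuals with fewer than 5 read-covered markers
  per Mb genome-wide are dropped before decoding (too little information
  for reliable mosaic reconstruction).
- **Double-crossover filter.** Crossover interference makes nearby double
  crossovers implausible (effectively absolute below ~5 Mb in large avian
  chromosomes). Internal decided segments shorter than 3 Mb flanked by
  decided segments on both sides are removed iteratively: flanks agreeing
  in state are merged (two crossovers removed); disagreeing flanks cause
  the short segment to be masked to UU (default) or absorbed leftward
  (option). Masking explains how the filter can lower the call rate. The
  filter is idempotent and never increases the crossover count.
- **Individual outliers.** Sample mix-ups and pedigree errors inflate
  apparent recombination. Default mode drops individuals whose decided
  call rate falls below 90% after the double-crossover filter; an
  alternative flags genome-wide crossover counts above
  median + 3 × 1.4826 × MAD. Both statistics are always reported.
- **Binning.** Mosaics are summarized into 1-Mb bins (terminal partial
  bins keep their true span); a bin is decided only when one decided
  segment covers it entirely — bins containing a crossover or touching UU
  are missing. R/qtl export codes HH/HL/LL/missing as A/H/B/−, with cM
  positions approximated as Mb × map rate (no linkage map is estimated
  here).

## Evaluation

Agreement with an external validation set (or simulated truth) is the
proportion of matching genotypes over *comparable* loci — both sources
decided — per individual across loci and per marker across individuals.
Loci in masked bins are excluded (and counted). Against simulated truth the
same bin-level comparison is used, plus the fraction of true crossovers
falling inside inferred breakpoint intervals.

## The simulator

The generator reproduces the study conditions end to end and carries full
ground truth:

- **Sites.** Placed uniformly at random. A fraction ``fixed_fraction``
  (default 0.028) is fixed for alternative alleles between lines; the rest
  segregates within each line with allele frequencies drawn independently
  per line from a symmetric Beta whose shape matches the configured founder
  heterozygosity h via E[2pq] = a/(2a+1) (default h = 1/3, i.e. uniform
  frequencies). Under these defaults a non-fixed site is incidentally
  family-informative with probability 2·E[p⁴]² = 0.08, so ~10.6% of all
  sites are informative per family and the total site density is set to
  ``informative_density_per_mb`` / 0.106 ≈ 7.5k/Mb for the default target
  of 791 informative markers/Mb. These defaults jointly reproduce the
  published relationships between line-fixed fraction (~3%), per-family
  informative fraction (10–14%) and total SNP density in a two-line
  livestock intercross.
- **Meiosis.** Per chromosome, the crossover count is Poisson with mean
  equal to the map length in Morgans (rate × length); positions are uniform
  subject to a hard minimum gap (default 5 Mb) by rejection sampling —
  interference as a hard exclusion window rather than a gamma renewal
  process, the simplest model consistent with the cytological statement it
  encodes. F1s carry one pure-H and one pure-L chromosome set, so an F1
  gamete's line origin is exactly its meiotic phase; F0→F1 meioses are not
  simulated because informative markers are homozygous within every
  founder, making them irrelevant to line origin.
- **Reads.** Simulated at marker sites only (the pipeline consumes site
  depths, not fragments): per-site depth is Poisson(coverage; default
  0.33), each read samples one of the two true alleles and flips with
  probability ``seq_error`` (default 0.005). Coverage sweeps use binomial
  thinning of a single high-coverage realization, which couples the
  datasets and makes accuracy-versus-coverage comparisons low-variance.
- **Determinism.** One ``numpy`` Generator seeded from ``seed`` drives
  everything; outputs are byte-identical across reruns.

What the simulator does **not** model: reference/mapping bias beyond the
flip probability, indels and multi-allelic sites, depth overdispersion and
batch effects, sex chromosomes, and non-uniform marker density along real
chromosomes (the published data show marked unevenness of line-fixed
markers). Passing simulation tests therefore demonstrates correctness of
the inference machinery under the stated generative model, not robustness
to alignment artefacts in real data.

## Numerical and design choices

- Coordinates are 1-based inclusive internally (VCF convention); BED
  exports convert to 0-based half-open.
- Windows are non-overlapping and the trailing partial window merges into
  the previous one; a chromosome with fewer markers than one window is a
  single window (warning).
- Sites with any missing founder call are excluded from that family's
  marker set: one missing call voids the fixation guarantee. Markers that
  are fixed in one line's founder pair but segregate in the other (which
  would add ~20% more partially informative markers) are deliberately not
  used.
- Pooled (line-level) selection uses a frequency slack δ (default 0 =
  strictly fixed): one allele at frequency ≥ 1−δ in H founders and ≤ δ in
  L founders.
- Reads supporting neither allele at a site are ignored (tallied in
  diagnostics); the model is biallelic throughout.
- Degenerate inputs: a chromosome with no markers or no reads yields a
  single UU segment; an all-missing founder site is excluded and counted;
  an empty breakpoint set yields an empty summary.
- ``--threads`` is accepted by the CLI for interface stability but
  execution is a serial per-individual loop; results are by construction
  independent of the requested thread count.

## Problem sizes used in the shipped checks

The accuracy/resolution checks simulate ten families on a five-chromosome
200-Mb genome at the default densities (the package's standard demonstration
scale for a skim-sequenced intercross); the coverage sweep uses six families
on a two-chromosome 60-Mb genome at coverages 0.05–0.4×; HMM decoding is
additionally verified against exhaustive path enumeration on chromosomes of
up to 12 markers, and marker selection against a brute-force predicate on
10,000 random sites.

## Known limitations

- The transition kernel approximates the exact F2 two-gamete model (see
  above); both are indistinguishable at informative-marker spacing.
- Founder phasing is not attempted; partially informative markers are
  discarded rather than exploited.
- The X/Z chromosome needs a dosage-aware model and is excluded from
  imputation by default.
- Joint decoding across siblings (sharing F1 recombinations) is not
  implemented; families are independent.
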