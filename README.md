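# beetmbs

Mapping-by-sequencing (MBS / bulked-segregant analysis) pipeline for
localizing a quantitative trait locus in a biparental F2 population from
pooled short-read sequencing of phenotypic extremes — modelled on the
design used to map the nematode-tolerance locus of sugar beet, where the
trait is the number of *Heterodera schachtii* cysts per plant.

It is aimed at plant geneticists who have (or want to simulate) a
segregating population, per-plant count phenotypes scored in incomplete
blocks, and a multi-sample VCF of the two parents, the F1, and extreme
phenotype pools.

## Method

1. **Phenotyping.** Cyst counts *n* are variance-stabilized as
   SN = √(n + 3/8). Box effects of the randomized incomplete-block design
   are removed by an additive two-way fit (line + block, alternating least
   squares); a line's *adjusted mean* is the mean of its block-adjusted
   plant values, and the within-line coefficient of variation (CV)
   screens F2:3 families for residual segregation. The 20 lowest and 16
   highest adjusted means among CV-eligible lines form the tolerant and
   susceptible pools.
2. **Variant filtering.** From a multi-sample VCF, biallelic SNVs are
   kept when (1) both parents are homozygous, (2) the parents contrast,
   and (3) the F1 is heterozygous — plus depth and QUAL guards. Each
   surviving site knows which allele came from the tolerant parent.
3. **dAF scan.** Per variant, the tolerant-allele frequency of each pool
   is computed from summed allele depths and the delta allele frequency
   dAF = AF_tol − AF_sus is averaged in tumbling windows of 10 SNPs per
   chromosome. Every maximal run of ≥ 5 consecutive complete windows with
   mean dAF > 0.5 becomes a candidate interval (the "50 SNP"
   delimitation). At a monogenic causal locus with perfectly opposite
   pools the dAF is ideally 1.
4. **Marker design.** KASP-style candidates are clean contrasting SNVs
   with no other (leniently called) variant within 50 bp, < 65% GC over
   the 100 bp of flanking sequence, per-contig quotas by call quality
   (1000 per chromosome, 4 per unplaced contig), and a final
   well-distributed subset by exact max–min spacing.
5. **Simulator.** A built-in generator produces the whole study shape at
   desk scale — 9 chromosomes, 406 F2 lines (Haldane meiosis), negative-
   binomial cyst counts with block effects, extreme pools, and ~20×
   Poisson/binomial allele-depth sampling emitted as VCF — with per-site
   ground truth for validation.

## Worked example

```sh
beetmbs all --outdir demo --seed 1
# done: 1 interval(s); outputs in demo (manifest.json)
```

The default configuration simulates the study-shaped population with a
single additive locus on chr5 near 10 cM. With seed 1, 2,025 simulated
sites enter the filter and 1,831 survive (93 rejected for a
non-homozygous parent, 101 for non-contrasting parents — the planted
decoy sites); the scan reports one interval:

```
chrom  start_pos  end_pos  first_window  last_window  n_windows  n_snps  max_mean_daf
 chr5       2834   494014             0            9         10     100      0.963344
```

The interval contains the true causal variant (chr5:120,248, recorded in
`truth.tsv` and flagged `in_interval: true` in `manifest.json`). The
genome-wide mean of window dAF away from the locus is ≈ 0.008 — noise
around zero — while windows over the locus approach the ideal value of 1.
`marker_panel.tsv` lists the spaced marker candidates with their
`flank[ref/alt]flank` KASP submission strings.

Per-stage commands (`beetmbs phenotype|filter|scan|markers`) run the same
steps on user-supplied TSV/VCF/FASTA files.

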