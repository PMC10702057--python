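# Methods

## Phenotype model and adjustment

Counts of nematode cysts per plant are treated as overdispersed counts;
the square-root transform SN = √(n + 3/8) approximately normalizes and
variance-stabilizes them. The greenhouse layout is a randomized
incomplete block design: plants sit in boxes, each box holding plants of
many lines, so box (block) effects are separable from line effects only
through the connectivity of the design.

`phenotyping.adjusted_means` fits the additive two-way model
`SN = line + block + residual` with lines and blocks as fixed effects by
alternating least squares: given block effects, line effects are per-line
means of the partial residual, and conversely; block effects are centered
to mean zero across blocks each sweep. Iteration stops when no effect
moves by more than 1e-10 (at most 200 sweeps). On a connected design this
converges to the two-way least-squares solution; on a *balanced* design
it coincides with mixed-model adjusted means, and under imbalance it
differs from an REML fit only by the absence of shrinkage — a deliberate
choice: the fit is deterministic, dependency-free, and exactly
reproducible. Disconnected designs are rejected with the offending block
groups named (connectivity via a bipartite line–block graph).

Adjusted plant values are `SN − block effect`; a line's adjusted mean is
the mean of its adjusted plant values, matching plant-level adjustment
rather than a fit on line means. The within-line CV (sample SD / mean of
adjusted plant values) flags segregating F2:3 families; the CV cutoff
(default 0.3) is a free parameter since no canonical value exists. CV is
undefined (NaN, excluded from pool eligibility) when a line's mean is
≤ 0, which on the SN scale only occurs after extreme block corrections.

Extreme pools default to 20 tolerant (lowest adjusted means) and 16
susceptible (highest) lines; ties are broken by lexicographic line id so
selection is invariant to input row order.

## Variant filter

Sites are biallelic SNVs only (indels and multiallelic records are
counted and dropped at ingestion). The confidence filter keeps a site iff
both parents are homozygous, the parents contrast, and the F1 is
heterozygous; in addition no parent/F1 genotype may be missing, each
parent's summed allele depth must reach `min_parent_depth` (default 5)
and site QUAL must reach `min_qual` (default 30). The depth/QUAL defaults
are declared substitutes for caller-specific hard filters, not
reconstructions of any particular pipeline, and are configurable.
Rejection accounting assigns each record to its *first* failing criterion
in the order: missing genotype, parent homozygosity, parental contrast,
F1 heterozygosity, parent depth, QUAL — missing genotypes are checked
first because homozygosity is undefined for them. Survivors carry
`tol_is_alt`, the orientation flag saying whether the tolerant parent is
homozygous for the ALT allele; everything downstream is computed on the
tolerant-allele axis.

## dAF scan

Pool allele frequency is tolerant-allele depth over total depth, with the
allele depths of all libraries of one phenotype class (individually
sequenced extreme lines plus combined pools) summed before division — no
per-library weighting. Sites where a pool's depth is below `min_depth`
(default 10) are masked; masked sites neither occupy window slots nor
shift window boundaries.

Windows are **tumbling** (non-overlapping) groups of exactly 10 unmasked
SNPs per chromosome: five consecutive windows then span exactly 50 SNPs,
which is what makes the run-of-five delimitation rule well defined. A
sliding mode (`step < window_size`) exists but is off by default. A
trailing window with fewer than 10 SNPs is reported with its true count
and flagged incomplete; incomplete windows are excluded from interval
detection.

The scan thresholds the **signed** window mean dAF (strictly > 0.5 by
default): orientation is known from the parents, and signing prevents
background noise from folding onto the positive axis. Every maximal run
of ≥ `run_min` (default 5) consecutive complete windows above threshold
becomes one candidate interval spanning the first window's first SNP
through the last window's last SNP (1-based inclusive internally; BED
export is 0-based half-open).

## Marker design

Candidates start from the confidence-filtered ("clean") set minus known
marker positions. A candidate fails `flank_variant` if any variant of a
lenient, unfiltered call set other than itself lies within ±50 bp (a
polymorphic flank breaks allele-specific PCR primers). "100 bp of
flanking sequence" is read as 50 bp per side — the same window as the
flank-variant check; GC is counted over the concatenated 100 bp and must
be strictly below 0.65. Candidates within 50 bp of a contig end or with N
in a flank fail `flank_n`. Per-sequence quotas keep the top 1000 (placed
chromosome) or 4 (unplaced contig) candidates by site QUAL, ties to the
lower position. Rules run cheap-to-expensive (existing marker → flank
variant → flanks/GC → quota) and each rejected candidate records exactly
its first failing reason.

The final "well-distributed" panel takes, per chromosome, the k-subset
maximizing the minimum pairwise spacing. In one dimension that minimum is
the smallest adjacent gap, so the optimum is computed exactly: binary
search on the achievable gap with a left-to-right feasibility sweep. This
replaces a greedy farthest-point heuristic considered first — the greedy
is only a ½-approximation and can be beaten by random subsets, whereas
the exact subset dominates every alternative k-subset by construction and
is equally deterministic. For k = 1 the candidate nearest the chromosome
midpoint is taken.

## Simulator

The generator reproduces the statistical structure the analysis assumes,
at desk scale:

- **Map.** 9 chromosomes, 225 variant sites each (~2,000 genome-wide),
  1 Mbp / 80 cM per chromosome with uniform recombination. Sites keep
  60 bp clear of chromosome ends so marker flanks always exist.
- **Meiosis.** F2 lines are fusions of two independent gametes of the
  heterozygous F1; crossovers between adjacent sites occur with the
  Haldane fraction r = (1 − e^(−2d/100))/2 — no interference, the
  simplest standard model and sufficient for method testing.
- **Phenotypes.** Line mean `max(0, baseline_mean − effect × dosage)`
  with defaults baseline 85 and effect 30 cysts per tolerant-allele dose,
  chosen to reproduce the reported adjusted-mean ranges of the extreme
  families (susceptible ≈ 66–101, tolerant ≈ 19–30 cysts); heterozygotes
  are exactly intermediate (purely additive). Counts are negative
  binomial with dispersion 5 (variance = μ + μ²/5; `inf` gives the
  Poisson limit); box effects are drawn N(0, 0.5²) on the
  SN scale (default SD 0.5), added to √(μ + 3/8) and back-transformed, negative means
  clamped to zero and logged. Dispersion and block SD are free parameters
  — the source study states no noise magnitudes — and were fixed once at
  greenhouse-plausible values.
- **Pool read depths.** Per site and library, depth ~ Poisson(coverage,
  default 20) and alt reads ~ Binomial(depth, q′) with
  q′ = q(1−e) + (1−q)e, e the per-read error rate (default 0.002). No
  read-level simulation: the analysis consumes AD fields only. Parents
  and F1 are emitted as fixed-genotype samples with sampled depths. A
  `decoy_fraction` (default 0.1) of sites is non-informative (monomorphic
  or heterozygous-parent) to exercise the filter; the truth table labels
  every site.
- **RNG.** One root seed; each stage (meiosis, blocks, phenotypes, site
  classes, reads, reference) derives an independent `default_rng([seed,
  stage_tag])` stream, so outputs are byte-reproducible and stages are
  perturbation-independent.

What the simulator does *not* emulate: linkage-map error, segregation
distortion, repeat-induced mapping artefacts, variable per-site coverage
bias, index hopping between pooled libraries, or multi-QTL architecture.
Passing tests therefore demonstrate correctness of the pipeline's
arithmetic and its power under an idealized monogenic design, not
robustness to those real-data pathologies.

## Problem sizes and numerical choices

The replicated power checks use the full study shape (406 lines × 10
plants, 9 × 225 sites, pools 20/16, 20× coverage) for 50 seeded
replicates per condition — about 0.1 s each — and the detection criterion
is containment of the true causal site in a detected interval. The
end-to-end example configs in the test suite use 2 chromosomes × 120
sites and 80 lines, enough for a stable five-window run over the locus.
Alternating least squares uses tolerance 1e-10 (effects are O(10), so
this is ~1e-11 relative); window means are plain arithmetic means;
interval boundaries use strict inequality (dAF > threshold) matching the
delimitation rule's wording.
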