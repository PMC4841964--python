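# Methods

## Poisson quantification of droplet digital PCR

A ddPCR well partitions restriction-digested template and a duplex PCR
mix across oil droplets; after end-point amplification each accepted
droplet is read positive or negative in the FAM (target CNV) and VIC
(reference housekeeper, C7orf28b) channels.  Template molecules land in
droplets independently, so the per-droplet copy count is Poisson and the
occupancy is estimated from the negative fraction:

    λ = −ln((N − N⁺)/N),        CN = ploidy · λ_t / λ_r   (ploidy = 2).

The reference assay sits at two copies per diploid genome in every
individual, so the ratio is copies per diploid genome.  Key numerical
choices:

- **Interval.**  The 95 % interval uses the delta method on
  ln(λ_t/λ_r): var(λ) = p/((1−p)·N) with p the positive fraction, summed
  over channels on the log scale, z = 1.96.  It is asymmetric on the CN
  scale and always positive.  A target channel with zero positives yields
  an exact zero estimate with a degenerate interval.
- **Degenerate channels.**  A fully positive channel (saturation) or an
  empty reference raises an error rather than returning ±∞: no downstream
  consumer can use such a call, and the wet-lab remedy (dilute, re-run) is
  outside the software's control.
- **QC floor.**  Wells with fewer than 8,000 accepted droplets are flagged
  `low_droplets` but never rejected — a typical well reads ~13,000
  droplets, and a flag preserves the analyst's discretion.
- **Droplet volume.**  Default 0.91 nL, used only to convert an occupancy
  to copies/µL.  It cancels in the CN ratio, and a test pins that
  invariance.
- **Duplicate assays.**  CNV_16.1 is measured by two assays; calls are
  merged by inverse-variance weighting (variances from the interval
  widths) with a pooled interval.  Calls more than 1.0 copy apart are
  flagged `assay_discordant`; the threshold is roughly two standard
  deviations of the inter-assay difference observed when both assays are
  well behaved.

## ΔΔCT relative quantification

qPCR estimates are relative: the sample's target-minus-reference Ct
difference is referenced to a calibrator individual of known diploid copy
number, `CN = 2·2^(−ΔΔCt)`, assuming perfect doubling per cycle
(efficiency 2.0; the simulator's efficiency is configurable but the
estimator's is fixed, as is standard for ΔΔCT).  Replicates aggregate by
the arithmetic mean of Ct.  The estimate composites four reactions — the
target and reference assays for both individuals, each in quadruplicate —
so the interval combines the four replicate standard errors in quadrature
on the ΔΔCt scale before exponentiation; calibrator error therefore
propagates into every sample's interval.  Replicate SDs above 0.5 cycles
flag `noisy_replicates`; singleton replicate sets flag `no_ci`.

## Genotype calling

Both loci behave as stable bi-allelic CNVs: per-chromosome allele values
(1 or 3 copies for CNV_14.3; 1 or 5 for CNV_16.1) whose pairwise sums
give the diploid classes {2,4,6} and {2,6,10}.  A continuous call is
assigned to the nearest class, with confidence the normalised Gaussian
weight of the estimate against all class centres using the call's
CI-derived SD (floored at 0.25 copies for degenerate intervals).

- **No-call rules.**  Estimates further than 1.5 copies from every class —
  half the smallest CNV_16.1 inter-class gap plus margin — and exact
  midpoints between classes return no call.  Ambiguity is surfaced, not
  forced: in 327 genotyped dogs the study design expects no intermediate
  totals, so an intermediate estimate is more plausibly a failed well than
  a new allele.
- **Ambiguity flag.**  When the runner-up class retains more than 0.2 of
  the best class's weight the call is flagged `ambiguous` but still made.
- **Class discovery.**  `discover_clusters` runs 1-D k-means for k = 2..5
  and keeps the k with the best silhouette score.  Centres within 0.35 of
  an integer are snapped to it; others are reported raw with a warning.
  Discovery returns the centres plus a decomposition into allele values
  when the centres form the arithmetic pattern {2a, a+b, 2b}.

## Pedigree checks

Called allele pairs are ordinary co-dominant markers, so each offspring
must be assignable one allele from each parent.  Fully genotyped trios
are checked strictly; trios with one genotyped parent are checked against
that parent only (offspring must share an allele with it) and reported
separately, because extended pedigrees are rarely complete.  The
two-locus check flags individuals whose genotype pair cannot be assembled
from two haplotypes respecting the canonical phase (14.3-allele-1 with
16.1-allele-5; 3 with 1).  The phase is inferred from the dominant
co-segregation pattern — the mapping under which the most doubly
genotyped individuals are consistent — with the hard-coded default as
fallback and override.

## Association statistics

All tests run on allele counts: `a, b` = case alleles carrying the risk
allele (CNV_16.1 allele 5) or not, `c, d` = the same for control alleles.

- Odds ratio `ad/bc` with Woolf interval
  `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`.
- Risk ratio `(a/(a+b))/(c/(c+d))` — allele-5 carriage frequency among
  case alleles over that among control alleles — with the Katz interval
  `exp(ln RR ± 1.96·√(b/(a(a+b)) + d/(c(c+d))))`.  This orientation is
  the unique standard one whose point estimate and interval both match
  the published table.
- Fisher two-tailed p by full enumeration: the sum of hypergeometric
  point probabilities (same margins) not exceeding the observed table's,
  with a `1 + 1e-7` relative tolerance on the comparison to stabilise
  floating-point ties.
- Zero cells receive the Haldane–Anscombe +0.5 correction on all four
  cells, flagged; no packaged table needs it.
- Report rounding follows the published presentation: two decimals for
  ratios and intervals, four for p-values.

### The packaged count fixture

`cnvdrop.table1` ships the published genotype counts per phenotype
(SPAID, fever, arthritis, vesicular hyaluronosis, otitis, amyloidosis;
affected/unaffected) at both loci.  Loading validates two structural
facts and raises on failure: every genotype column sums to the published
cohort size (155/34, 114/51, 79/46, 44/58, 34/71, 31/17), and the
published allele rows equal the linear map `count(a) = 2·n(a/a) +
n(a/b)`.  The SPAID-negative column is control group C1; the
amyloidosis-negative column is C3, used for the amyloidosis comparison
because only those controls were histopathologically confirmed
amyloid-free.

**Known inconsistency.**  The five sub-phenotype columns of the published
risk/odds table reproduce exactly from these counts, but the SPAID column
does not: the counts give OR 4.30 (2.29–8.07) and RR 1.33 where the
publication prints 4.10 (2.48–6.74) and 1.31.  The discrepancy is in the
source (possibly a different case set or a typographical slip) and cannot
be resolved from the printed counts; this package reports what the counts
imply and excludes the SPAID column from its reproduction suite.

## The synthetic-data generator

Defaults encode the study conditions the pipeline expects:

| parameter | default | rationale |
| --- | --- | --- |
| accepted droplets | N(13,000, 800²) | ~13,000 droplets read per well |
| reference occupancy λ_r | 0.619 copies/droplet | ≈ 6,000 of 13,000 wells VIC-positive |
| template-load CV | 0.08 | well-to-well pipetting/digestion variation, shared by both channels |
| Ct noise | 0.15 cycles/replicate | puts qPCR estimates in the smeared-continuum regime while ddPCR stays clustered |
| canonical haplotype frequency | 0.80 | random mating gives two-locus pair frequencies ≈ 64/32/4 %, matching the observed 64.5/30.3/4.3 pattern |
| recombination rate | 0.01/meiosis | placeholder; the true inter-CNV rate is unknown, but small enough that recombinant pairs stay rare |
| penetrance by allele-5 dosage | (0.18, 0.50, 0.82) | chosen analytically so the population allele-level OR ≈ 4 (see below) |

Penetrance derivation: with haplotype frequency f = 0.8 the genotype
frequencies are 0.64/0.32/0.04; allele-level case and control counts
under penetrances (f₀, f₁, f₂) give
OR = [(2·0.64·f₂ + 0.32·f₁)/(0.32·f₁ + 2·0.04·f₀)] ÷ the analogous
control ratio.  (0.18, 0.50, 0.82) yields OR = 4.01.  Individual cohorts
realise noisy ORs (a 34-control group carries wide sampling error), so
the generator records its own realised allele table and OR, and recovery
is judged against that bookkeeping rather than the population value.

Randomness: every operation takes a `numpy.random.Generator`; a fixed
seed determines all output, and nested simulations consume the same
stream in documented call order.

What the generator does **not** emulate: droplet fluorescence amplitudes
and "rain" (inputs are already-classified counts), droplet coalescence,
restriction-digestion kinetics, qPCR efficiency drift or multiplex
competition, genotyping error in pedigree founders, and any genetic
architecture beyond the single two-locus system (no polygenic background,
no environmental covariates).  Passing tests therefore demonstrate that
the estimators and checks are correct under the stated statistical model,
not that real assays are free of the chemistry-level artefacts above.

## Problem sizes used in the reproduction suite

Association statistics run on the packaged counts (instant).  Simulation
checks use 1,000 wells per copy-number class for recovery, 200 replicate
cohorts of 50 individuals for the precision ordering, a 200-call cohort
for cluster discovery, ten 4-generation pedigrees (~350 individuals each)
for Mendelian consistency, 1,000 random tables for Fisher agreement, and
a 155-case/34-control cohort for the end-to-end chain — sizes at which
every Monte-Carlo margin in the suite is comfortably stable.

## Known limitations

- The merge step weights duplicate-assay calls on the linear CN scale;
  for very low copy numbers a log-scale merge would be marginally better
  behaved, but published classes sit at 2–10 copies where the difference
  is negligible.
- The qPCR interval ignores inter-batch calibrator drift (one calibrator
  measurement per assay batch is assumed representative).
- `discover_clusters` assumes roughly equal within-class dispersion;
  strongly heteroscedastic inputs can bias the silhouette-chosen k.
- The two-haplotype consistency rule detects recombinant *carriers*; it
  does not phase or locate the recombination event.
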