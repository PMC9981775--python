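# Methods

This note documents the models behind `boarpop`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic-data tests
do and do not demonstrate about real data.

## Data model

Genotypes are diploid, biallelic dosages in {0, 1, 2} counting copies of a
per-locus *counted allele* (`allele_b` of the marker map), with a reserved
missing sentinel that never participates silently in arithmetic.  PED/MAP
text files do not declare which allele to count; on reading, the counted
allele defaults to the lexicographically second observed allele and can be
pinned with a reference-allele table.  Every dosage-level statistic that
should not depend on this arbitrary orientation (MAF, Hamming distance,
MLH) is verified to be invariant under the flip d → 2 − d.  Marker
positions are 1-based base pairs; BED gene intervals are stored native
(0-based half-open) and converted only at the membership test, so both
conventions stay unambiguous.

## Quality control

Defaults reproduce standard beadchip practice for this organism: locus and
sample call rate ≥ 0.95 (loci filtered first, so a batch of bad loci does
not take samples down with it), MAF > 0.025, windowed LD pruning with a
50-SNP window advancing by 5 SNPs against an r² ceiling (0.5 for the ROH
panel, which tolerates moderate LD; 0.2 for the structure panel), and
removal of related individuals at pairwise π̂ ≥ 0.183 computed within
sampling location on loci with within-location MAF > 0.10.  The 0.183
cutoff is kept as a plain configuration constant (between the expectations
for second- and third-degree relatives).

Relatedness uses the classical method-of-moments IBS→IBD estimator: the
observed counts of IBS 0/1/2 over pairwise-complete loci are equated to
their expectations given sample allele frequencies under IBD state 0/1/2;
negative solutions are truncated to zero and renormalised, and
π̂ = P(IBD=2) + ½·P(IBD=1) is clamped to [0, 1].  Small-sample bias
corrections of the classical tool are omitted; at the panel sizes involved
(thousands of informative loci) the estimator is comfortably accurate for
a 0.183 screen (duplicate pairs score exactly 1, simulated
parent–offspring pairs score 0.5 ± 0.02).

LD pruning resolves an over-threshold pair by dropping the lower-MAF
member (ties: the later map position), always attacking the currently
largest r² first.  This makes the retained set deterministic for a given
input order; the exact tie-break differs between published tools and is
not material to any downstream statistic.

## Hybrid index (F_hybrid)

The estimator is transductive: `fit` receives the combined panel (observed
wild samples plus a domestic-pig reference pool) and

1. estimates wild allele frequencies per genetic cluster
   (`cluster_id` in the sample table; one pooled cluster when absent),
2. simulates `n_pure` = 20 unadmixed genotypes per cluster,
   dosage ∼ Binomial(2, p) — note p is the frequency of the *counted*
   allele, not the folded MAF, so the simulation stays
   orientation-consistent (equivalent when the dosage counts the minor
   allele),
3. computes pairwise Hamming distances — Σ|dᵢ − dⱼ| over
   pairwise-complete loci, normalised by twice their number, so opposite
   homozygotes count 2 and d ∈ [0, 1],
4. ordinates by classical PCoA (double-centre −½·J·D²·J; coordinates are
   eigenvectors scaled by √λ; negative-eigenvalue mass is reported, never
   silently dropped into the coordinates), and
5. projects every sample on the line from the simulated-pure centroid
   (score 0) to the pig centroid (score 1).

Scores are intentionally *not* clamped to [0, 1]: overshoot and
undershoot carry diagnostic information.  Classification uses the raw
score with the pedigree-expectation boundaries
(< 0.0625 none; 0.0625–0.125 4th generation; 0.125–0.250 3rd; > 0.250 2nd
or closer).

**Axis selection.**  How many ordination axes should host the projection
is genuinely open.  Two regimes pull in opposite directions.  On a panel
whose leading axis *is* the pig–wild contrast, adding further axes only
admits nuisance directions; in particular, the simulated-pure anchor is
slightly under-dispersed relative to real samples (its generating
frequencies are estimates, and E[p̂(1−p̂)] < E[p(1−p)]), which manifests as
a real, systematic ordination axis separating the anchor from everything —
including it tilts the polar axis and inflates all scores by several
hundredths.  On a strongly structured panel, conversely, the leading axis
may be a wild cline and a fixed one-axis projection is simply wrong.  The
default `axes='auto'` therefore keeps the axes on which the pig pool
separates from the *observed wild* centroid by at least 6 standard errors:
wild-structure axes fail this because wild spread inflates the SE, and the
pure-anchor nuisance axis fails it because pigs and wild sit on the same
side.  Fixed integer axis counts remain available for comparison with
other analyses.

A known, method-inherent behaviour retained by design: wild clusters that
are genuinely closer to pigs in ordination space receive elevated scores
relative to the single pooled pure anchor.  This mirrors the elevated
median projection scores reported for strongly diverged southern European
wild-boar clusters and is a property of the projection construction, not
an implementation artifact.

**Diagnostic alleles.**  A locus is diagnostic when one of its alleles has
wild-pool frequency < 0.025 while that same allele exceeds 0.225 in the
pig pool.  A per-sample profile reports the carried fraction of diagnostic
loci and a genomic clustering score (maximum carried count in any 10-Mb
window); its permutation p-value shuffles *which* diagnostic loci are
carried while fixing the carrier count, so it tests spatial arrangement,
not introgression load, with the add-one correction.

## Runs of homozygosity (F_ROH)

Detection follows sliding-window semantics: a window of 70 consecutive
SNPs passes with zero heterozygotes and at most 5 missing calls; a SNP
joins a candidate run when ≥ 5% of the windows covering it pass; candidate
runs are trimmed to homozygous end-SNPs, split at inter-SNP gaps above
500 kb, and kept if ≥ 5 Mb long with ≥ 50 SNPs and mean density at least
1 SNP per 150 kb.  Segment boundaries are the outermost homozygous SNPs,
so the 5-Mb filter applies to the physical homozygous extent, not window
edges.  The window size, zero-heterozygote rule and segment criteria are
the method's defining parameters; the hit proportion (0.05) and the
missing allowance (5) follow the conventional tool defaults and are
configuration-exposed, flagged as assumptions in the run log of the
pipeline.

The F_ROH denominator is the *scanned genome*: per chromosome, markers are
split at gaps above 500 kb, and within each dense stretch the union of all
marker intervals that could host a qualifying segment is accumulated.
With a 5-Mb cutoff this denominator, not the assembly length, is the
honest basis of the "fraction of the genome in ROH"; an assembly-length
denominator is available by passing the total explicitly.  Classification
thresholds 0.125 / 0.0625 / 0.03125 are the expected autozygosity of
offspring of half siblings, full cousins and half cousins.

On windowless exhaustive enumeration the windowed detector is exactly
equivalent when the missing allowance is 0 and the hit threshold is
vanishing; this equivalence is asserted on random instances in the test
suite and the acceptance script.

## Spatial structure

The structure stages run on the stringently pruned intergenic panel after
excluding hybrid (F_hybrid > 0.0625) and inbred (F_ROH > 0.0625) samples
and downsampling to at most 5 individuals per sampling location (seeded).

* **Isolation by distance.**  Mantel correlation between genetic and
  great-circle (haversine, R = 6371 km) distance.  Default operates at
  population level (mean between-location genetic distance) to damp
  spatial autocorrelation; individual-level matrices are accepted.  The
  permutation p-value is two-sided with the add-one estimator
  (1 + #{|r*| ≥ |r|}) / (1 + n_perm); at n ≤ 7 an exact mode enumerates
  all n! relabelings (p = count / n!, identity included).  Under a
  permuted-label null, the empirical type-I error at α = 0.05 is
  calibrated within [0.03, 0.07] by construction of the add-one estimator
  with n_perm = 199.
* **Axis–geography correlations.**  Spearman rho of per-location mean
  ordination scores against longitude and latitude (all four pairs of the
  first two axes reported); constant scores yield a flagged NaN rather
  than an arbitrary value.
* **MLH model.**  MLH = heterozygous / typed loci.  The linear model is
  OLS of MLH on longitude, F_hybrid and F_ROH with a condition-number
  guard (> 1e10 errors out); latitude is screened in a separate univariate
  model rather than entering the main design.
* **Regional alleles.**  The phrase "minor-allele frequency within the
  focal region larger than 0.5" is self-contradictory if "minor" is
  defined within-region; it is implemented as: the allele that is minor at
  *panel* scale whose *within-region* frequency exceeds 0.5 (locally
  major).  Monomorphic panel loci are skipped.  Per-location mean
  frequencies of the selected alleles feed the interpolation.
* **Kriging.**  Coordinates are projected to planar kilometres by an
  equirectangular projection about the mean latitude (adequate at
  continental extents for interpolation purposes).  The variogram is
  auto-fitted: binned empirical semivariance to half the maximum distance,
  weighted least squares (pair counts as weights) over spherical,
  exponential and gaussian families, best weighted SSE wins; exponential
  and gaussian ranges are parameterised as practical ranges.  Ordinary
  kriging solves the variogram-form system with a Lagrange multiplier;
  weights sum to one by construction, duplicate points are averaged first,
  and with a zero nugget the surface interpolates the data exactly (to
  solver precision).  A constant field degenerates to the mean predictor
  with a flag.  The default grid is 0.5° over the location bounding box
  with a 10% margin.

## Synthetic data generator

The generator defines the conditions under which the package is tested.

* **Divergence.**  Balding–Nichols: ancestral p ∼ Uniform(0.05, 0.95),
  population frequency ∼ Beta(p(1−F)/F, (1−p)(1−F)/F), so
  Var = F·p(1−p); F = 0 copies the ancestral values.  Wild populations use
  F = 0.05; the pig pool uses F = 0.15 against the wild mean, large enough
  for a clean polar axis and in line with strong wild/domestic
  differentiation on these arrays.
* **Cline.**  Population locations are projected on a direction vector;
  frequencies shift on the logit scale proportionally to the centred
  projection, with the sign alternating by locus parity so the panel-wide
  frequency profile stays balanced while isolation by distance emerges.
  The operation is deterministic given the frequencies (no hidden seed).
* **Genome and recombination.**  18 pig-like autosomes (≈ 2.26 Gb) at
  1 cM/Mb (≈ 23 Morgans).  Meiosis draws Poisson(length in Morgans)
  crossovers with uniform positions (Haldane, no interference) — the
  simplest model with correct expectations for tract lengths and counts at
  this scale.  Founder haplotypes are labelled uniquely; transmission
  tracks the label mosaic, so the true pig-ancestry fraction and the true
  autozygous tracts (equal labels on both homologues) are exact, not
  estimated.
* **Pedigrees.**  Builders for backcross depth g (F1 backcrossed g−1
  times; expected pig ancestry 2⁻ᵍ), and half-sib, full-sib, full-cousin
  and half-cousin matings (expected F = 1/8, 1/4, 1/16, 1/32).  A
  recursive-kinship oracle in the test suite independently confirms these
  expectations against the simulated means.
* **Missingness** defaults to 1%, typical of post-genotyping beadchip
  data; the panel is calibrated so that > 90% of loci survive the standard
  call-rate and MAF thresholds at the generator's sample sizes.
* **Diagnostic loci.**  Arrays ascertained on domestic breeds contain
  variants nearly absent in wild populations; the benchmark generators
  plant ~2% of loci at wild frequency 0.005 and pig frequency 0.40 so the
  diagnostic-allele stage has realistic targets.
* **Marker density** defaults to 1 per 100 kb (120 kb in the combined
  fixtures) so the ROH criteria (50 SNPs / 5 Mb / 150 kb density) are
  satisfiable.

**What passing tests show — and what they do not.**  The generator
produces unlinked loci within populations (apart from pedigree-induced
haplotype structure), exact Hardy–Weinberg proportions, uniform marker
spacing and missingness that is independent of genotype.  Real
beadchip data have background LD, ascertainment-biased frequency spectra,
genotype-dependent missingness and uneven marker coverage.  Consequently
the tests validate the *estimators* (their contracts, invariances,
calibration and their recovery of pedigree expectations under the stated
model), not the field accuracy of any particular threshold on a real
panel.

## Problem sizes and runtime choices

The validation suite runs the hybrid-index recovery at 5,000 loci with 50
offspring per backcross depth, pedigree autozygosity at 200 offspring per
relationship class over the full 23-Morgan genome, ROH oracle equivalence
on 100 random 200-SNP instances, Mantel calibration at 500 replicates of
20 locations with 199 permutations, and the end-to-end pipeline on a
3-chromosome fixture.  These sizes keep each stage's Monte-Carlo error
well inside the tolerance it is tested at.

## Known limitations

* The relatedness estimator omits the classical small-sample bias
  corrections; with < 100 informative loci it warns rather than corrects.
* PCoA is dense eigendecomposition: fine for hundreds to a few thousand
  samples, not for biobank scales.
* The hybrid index assumes the wild panel is *mostly* unadmixed, since
  pure genotypes are simulated from observed wild frequencies; a heavily
  admixed cluster drags its own anchor toward the pigs.
* Kriging ignores coastline/landmass masks; surfaces extend over water.
* Only diploid biallelic loci, unphased; no VCF/binary PLINK input.
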