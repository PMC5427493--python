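# Methods

This note records the models, estimators, numerical choices and known
limitations behind the package, in the order the pipeline runs them.

## Study design being modeled

The pipeline targets a case/control contrast of two metapopulations living
under different climates: samples are labeled with a climate `zone`
("case" = high ambient temperature, "control" = low), a `subpopulation`
(breed/country within a zone) and long-run climate covariates (30-yr mean
temperature in °C and precipitation in mm).  All statistics treat the zone
labels as the two populations; subpopulations enter only through the
simulator and the latent-factor correction.

## Quality control

Filters run in a fixed, logged order: (1) duplicate (chrom, pos) removal
(keep-first by default; `drop-all` available), (2) per-sample call rate
≥ 99%, (3) per-variant call rate ≥ 99%, (4) minor allele frequency ≥ 0.05
computed on the retained samples, (5) autosome restriction (numeric
chromosome labels; X/Y/Z/W/MT excluded).  A record removed by several rules
is attributed to the first applicable rule so the log always balances.  The
order itself is a convention — the data do not determine it — and is fixed
so that removal counts are reproducible.

## PCA

The relationship matrix is `G = ZZ'/m` with `Z_ij = (x_ij − 2p_j)/
√(2p_j(1−p_j))`; missing genotypes are mean-imputed (zero after centering),
monomorphic variants are skipped with a warning rather than dividing by
zero.  Eigenpairs come from a dense symmetric eigendecomposition; a small
negative eigenvalue from floating-point round-off is clipped at zero.

## Weir–Cockerham F_ST

Per site, the r = 2 variance components a (among populations), b (among
individuals within populations) and c (within individuals) are computed from
sample sizes, alt-allele frequencies and observed heterozygote frequencies;
θ̂ = a/(a+b+c), undefined when the denominator is non-positive or the site
is monomorphic overall.  Small negative θ̂ is a property of the estimator
and is kept.  Hudson's estimator is available as a cross-check.  For
*multi-locus* summaries the ratio-of-sums Σa/Σ(a+b+c) is used: the mean of
per-site ratios is biased low by O(1/n), which is measurable at these sample
sizes, while the ratio of sums tracks the drift expectation
1 − (1 − 1/2N)^t within Monte-Carlo error.

Windows are 100 kb with a 50 kb step, anchored at coordinate 0 on every
chromosome, extending to the last scored site; sites with undefined θ̂ are
excluded from window means rather than zero-filled (zero-filling biases
peaks downward near monomorphic stretches).  A peak is a local-maximum
window with mean ≥ 0.2; its base is the maximal contiguous run of windows
above the genome-wide mean of window means (the `half-apex` rule is an
alternative), and overlapping bases merge.

## EHH, iHS and Rsb

EHH at marker x for carriers of a core allele is the probability that two
random carrier haplotypes are identical at every site from the core to x
inclusive.  It is computed by incremental partition refinement; haplotypes
falling into singleton identity classes contribute no pairs and can never
rejoin a class, so they are pruned as the walk proceeds (the per-step cost
then tracks the decaying haplotype homozygosity; the inner loop is
numba-compiled).  Walks stop below EHH = 0.05 (REHH's default, exposed),
at inter-marker gaps over 200 kb (side truncated and flagged, keeping
marker-sparse regions scorable), or at the chromosome end.  EHHS pools all
haplotypes and renormalizes by the core-site homozygosity.

iHH/iES integrate the decay by trapezoid over physical distance, linearly
interpolating the crossing of the cutoff level.  Physical bp is the map
unit (array data carry no genetic map); the ln-ratio statistics are
unit-invariant.

iHS = ln(iHH_ancestral/iHH_derived), standardized to mean 0 / SD 1 within
derived-allele-frequency bins of width 0.025.  **Standardization pools
sites genome-wide, not per chromosome**: a sweep drags dozens of linked
hitchhikers into its own frequency bin, and a per-chromosome bin would then
be dominated by the sweep itself, cancelling the signal.  Two-sided normal
p-values are attached; the operative significance rule is |score| ≥ 3.89
(two-sided p ≤ 1×10⁻⁴).  Alternative thresholds: BH step-up on p-values,
and a max-|score| permutation quantile for which the caller supplies the
permutation mechanism (B < 100 is refused as unstable).  Allele polarity
comes from the ancestral-allele annotation (the simulator's founder state);
without it the minor allele is treated as derived with a warning — this
flips signs only, not |iHS|-based calls.

Rsb = ln(iES_A/iES_B) on the shared site set, centered by the median
(mean optional) and scaled by the SD.

## ROH and landscape ROH

Detection follows the PLINK 1.9 sliding-window algorithm with the study's
parameters: 50-SNV windows moving one SNV at a time, a window passes with
≤3 heterozygous and 0 missing calls, a SNV is eligible when ≥5% of the
windows containing it pass, maximal eligible runs are split at gaps >1 Mb,
trimmed to homozygous endpoints, and kept if they have ≥100 SNVs, ≥1 kb and
≤50 kb/SNV density.  The "≤3 heterozygotes" rule is applied per scanning
window (PLINK's flag semantics), not per final segment.

Pools are single-linkage clusters of positionally overlapping segments per
chromosome; the consensus is the intersection of member intervals (pools
emptied by intersection are dropped before classification); members are
partitioned into allelic-match groups by ≥95% identity of homozygous
genotypes over consensus SNVs (connected components of the pairwise match
graph; het/missing sites are excluded from the concordance denominator).
A pool becomes a landscape-ROH call iff (a) consensus ≥1 kb, (b) the
consensus is covered by every member, (c) members are ≥5% of their zone's
samples, (d) all members share one zone; all four flags are always reported
for audit.

At desk scale the pooling step has an important behavior worth knowing:
with a few hundred diploids, background autozygosity from drift covers
enough of every chromosome that single-linkage pools chain into
chromosome-wide clusters whose consensus is empty, so zone-unique LROH
calls are rare or absent in simulation.  This mirrors the real-data regime
only qualitatively (real panels yield thousands of localized pools of which
a handful are zone-unique); the classification rules are therefore also
validated directly on constructed pools with known answers.

## Latent-factor environmental association

Per run, each standardized genotype column is regressed on the covariate
with an intercept and the top-K left singular vectors of the standardized
genotype matrix as nuisance covariates; the t statistic (df = n−K−2) is
mapped to the normal scale by z = Φ⁻¹(F_t(t)).  Run-to-run variation is
generated by seeded bootstrap resampling of samples (factors re-estimated
per resample); runs are merged by the per-SNV median z.  This is a
deterministic latent-factor-regression analogue of MCMC-based latent factor
mixed models: the residual confounding it leaves is handled exactly as in
the study workflow, through the genomic inflation factor
λ = median(z²)/0.4549 (0.4549 = χ²₁ median to 4 dp; a fixed λ can be
supplied instead).  Adjusted p = P(χ²₁ ≥ z²/λ), BH q-values, candidates at
q ≤ 0.1.  Variants monomorphic within the analyzed samples are excluded
from scoring and from λ — scoring them as z = 0 would deflate the median.
K is user-supplied; a scree helper reports leading variance fractions but
performs no automatic selection.

A structural limitation, demonstrated in the test suite: when the covariate
is collinear with population structure (a subpop-level covariate over
strongly drifted subpopulations), λ inflates to several-fold and no
genomic-control rescaling can restore power — this is a property of the
design, not of the implementation.

## Regions and enrichment

Hits expand to [pos−2 Mb, pos+2 Mb) clipped at zero; interval hits (LROH)
flank their first/last SNV, so a planted span of w bp yields a w+4 Mb
window.  Gene overlap is any-overlap (≥1 bp) on 0-based half-open
coordinates with strand ignored; GFF3 (1-based closed) is converted on
read.  Enrichment is the one-sided hypergeometric upper tail of the overlap
between a gene list and each GMT set (intersected with the universe), BH
across sets, with the FDR level chosen per source list (0.05 for iHS/ROH
lists, 0.1 for Rsb lists, following the study's convention).

## The simulator and what passing tests mean

Forward Wright–Fisher diploids with multiplicative fitness (1+s) per sweep
allele, per-zone selfing probability, Poisson crossovers (default
3×10⁻⁸/bp/gen ≈ 3 cM/Mb, the chicken genome-wide average) and symmetric
recurrent mutation (10⁻⁶/site/gen at array-like site densities).  Founders
are drawn at linkage equilibrium with frequencies from the neutral SFS
(P ∝ 1/i); the founder allele defines "ancestral".  Two phases: independent
zone drift, then independent subpopulation drift.  Environmental covariates
are zone means with a deterministic subpopulation spread plus individual
noise.  Planted truths: sweeps (standing variant on one shared founder
background, or a single mutant copy, with conditional re-runs from a
checkpoint if lost and a target-frequency stop that switches selection off
— a controlled incomplete sweep), ROH (one haplotype copied over the other
across an interval, delimited by explicitly heterozygous flank sites that
mark the truth boundary), and an environmental SNP whose per-individual
allele frequency tracks temperature between 0.05 and 0.95.

Scenario study conditions (fixed defaults; problem sizes chosen for
single-workstation runs):

* **neutral** — 2 × 500 diploids, 3 × 10 Mb × 22k sites, 50 generations of
  zone drift.  At 2N = 1000 the coalesced-pair fraction (≈0.049) sits at
  the EHH cutoff, so neutral EHH walks truncate quickly; smaller
  populations put a >5% identity floor under every walk, which is a drift
  artifact rather than a property of the statistic.
* **sweep** — 2 × 300 diploids, 12 × 10 Mb × 2.5k sites, 15 generations,
  one sweep (s = 0.15, p₀ = 0.15, 500 kb shared background, stop at 60%).
  The many-chromosome genome keeps the sweep's hitchhikers a small fraction
  of each frequency bin; the 500 kb background matches the ±500 kb Rsb
  localization scale.
* **inbred** — default 2 × 5 × 30 structure, selfing 0.9 in the case zone,
  two planted ROH (1.5 Mb and 1.2 Mb) in 12 and 10 carriers.
* **environmental** — default structure with a 1-generation subpopulation
  phase (mild within-zone structure) and the planted temperature SNP; the
  analysis uses K = 1 within the case zone.

What the simulator does **not** emulate: realistic chicken genome maps and
marker ascertainment, overlapping generations, migration between zones,
background selection, genotyping error and missingness patterns (missing
data paths are exercised by constructed fixtures instead).  Passing the
recovery tests therefore shows the statistics detect the signals they are
defined to detect under their own model assumptions — not that the
thresholds transfer to any particular real panel.

## Reproducibility

Every stochastic component takes an explicit integer seed and flows through
`numpy.random.default_rng`; identical configurations give byte-identical
outputs.  The pipeline manifest records parameters, seeds, stage timings
and sha256 checksums of every output file.
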