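# Methods

This note documents the models, estimators, numerical choices and known
limitations of `divcomp`, in the spirit of a statistical software
methods appendix. Empirical statements below are the ones the test
suite and `scripts/acceptance.py` themselves compute.

## The estimation problem

Two marker systems measure "genetic diversity" of the same populations
on different scales. Microsatellites are few (≈ 19 loci), multi-allelic
and hyper-mutable; genotypes are observed per individual. Pool-Seq
yields allele *frequencies* at millions of biallelic SNPs, but no
individual genotypes: per site and population one observes read counts
whose sampling chain is genomes → pool → reads. The package implements
the estimators appropriate to each data type and the statistics used to
compare them, plus a down-sampling analysis of how many SNPs a given
accuracy requires.

## Synthetic data model (`divcomp.synthio`)

The generator emulates the study design the pipeline targets: 9
populations × 20 diploids (pools of n = 40 haploid genomes), mean
coverage 60× (range printed in the emulated study: 52.7–69.3×),
sequencing error 10⁻³ per base, pairwise differentiation of a few
percent, genome-wide SNP-H_e ≈ 0.12–0.16 and exonic θ ≈ 0.009.

**SNP panel** (`simulate_snp_pools`). Per site: ancestral minor
frequency p₀ from a truncated neutral-like law with density ∝ 1/p on
[p_min, 0.5], p_min = 1/(9n) = 1/360 (mirroring the rare-variant mass a
joint SNP-calling step over nine pools can see); population frequency
p_j ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F) (Balding–Nichols, F = 0.05); pool
count a_j ~ Bin(n, p_j); coverage C_j ~ Poisson(60); minor reads ~
Bin(C_j, a_j/n); each read flips to a uniformly chosen other base with
probability ε, so tri-allelic artifacts exist for the biallelic filter
to reject. Balding–Nichols was chosen over a coalescent simulator
because it gives closed-form expectations (E of the Weir-style F̂ equals
F up to sampling terms; E[H_e] integrates in closed form against the
1/p law, 0.143 at the defaults) with no external dependency.

**Gene panel** (`simulate_gene_pools`). For Watterson/Tajima recovery
every exonic position is drawn, monomorphic or not: a position carries
i of n derived copies with probability θ/i (the neutral frequency
spectrum of a sample of n; exponent configurable via `gene_sfs_skew` to
produce rare-variant excess and negative Tajima's D without a
demographic model). Genes are 500 bp single exons with 100 bp spacers;
2,000 genes by default. Sites are independent — no linkage model, which
matches the emulated study's finding that linkage effects on
genome-wide summaries are negligible, but means the generator cannot
produce linked-selection artifacts.

**Microsatellites** (`simulate_ssr_genotypes`). Per locus, A alleles
(cross-species loci draw A ∈ [2,4], species-specific A ∈ [4,6] —
ascertainment made the species-specific class more polymorphic) with
symmetric-Dirichlet ancestral frequencies. Population j draws its
frequencies from Dirichlet(p₀ (1−F_jl)/F_jl). Two levels of drift
heterogeneity are modelled:

- a **population** drift level F_j solved from a target expected-
  heterozygosity ladder via E[H_e,j] = (1−F_j) × (mean ancestral gene
  diversity); the default ladder spans 0.32–0.46, the range the
  reference populations exhibit. Under pure drift a population cannot
  exceed ancestral diversity, so drift is floored at 1% and unattainable
  targets compress;
- a **locus** level: F_jl ~ Beta(F_j ν, (1−F_j) ν) with ν = 1,
  preserving E[F_jl] = F_j. Real microsatellite panels show exactly this
  genealogical spread (per-locus F_ST from ≈ 0.02 to ≈ 0.4 and
  per-marker H_e from near 0 to ≈ 0.7 in the reference study); ν was set
  from that printed spread. Without it, simulated population differences
  are implausibly consistent across loci and few-marker tests look far
  more powerful than real ones.

Genotypes add inbreeding f (identical-by-state pair forced with
probability f) and a null allele at frequency r (default 0.05, chosen so
null/null blanks reproduce the ≈ 0.3% missing-data rate of a curated
panel): null/visible shows as an apparent homozygote, null/null as
missing.

All randomness descends from one seed; each stage (alleles, reads,
bases, …) uses a child seed derived from the stage name, so re-running
any stage alone is bit-reproducible, and paired experiments (e.g. same
pools at doubled coverage) are possible.

## Estimators

**SSR-H_e** uses the Nei (1978) correction (2n/(2n−1))(1−Σp²) by
default (`bias_correction="raw"` available); with n = 20 the correction
is ≈ 2.5%. **A_r** is the raw mean allele count — the emulated design
has equal samples, so rarefaction is unnecessary; a hypergeometric
rarefaction variant exists for unequal samples (`rarefy=True`).
Missing genotypes are handled complete-case per locus: the individual is
dropped at that locus only.

**G_IS** = 1 − ΣH_o/ΣH_s over loci (ratio of sums; H_s Nei-corrected).
The permutation null re-pairs alleles among typed individuals within
each locus, preserving allele frequencies while destroying genotypic
association; p is one-sided for heterozygote deficiency with the
(1+b)/(1+m) estimator, so p > 0 always. Verified against exhaustive
enumeration of all 105 labelled pairings on a 4-diploid instance.

**Null-allele EM**: observable classes are heterozygote (i,j), apparent
homozygote (i) = true (i,i) ∪ (i,null), blank = (null,null). E-step
splits apparent homozygotes by p_i²/(p_i²+2p_i r); M-step counts
alleles. Initialisation r₀ = 0.05 with observed frequencies; convergence
on log-likelihood change < 10⁻⁸ (at the r = 0 boundary convergence is
linear, so the attained r scales like the square root of the tolerance —
a tighter tolerance is used when asserting r̂ ≈ 0). Non-convergence
raises an error carrying the last iterate. Verified against a
profile-likelihood grid search with independently coded likelihood.

**WC84 F_ST**: the 1984 variance components per allele and locus with
unequal sample sizes, combined as Σa/Σ(a+b+c) (ratio of sums —
Weir & Cockerham's own recommendation; the alternative average-of-ratios
is not offered because the source analyses' choice is undocumented and
ratio-of-sums is the field default). Negative estimates are reported as
computed. Verified to 10⁻¹⁰ against an independent scalar
implementation.

**SNP calling**: coverage = A+T+C+G reads only; a site is kept iff every
population's coverage lies in [20×, 400×] and exactly two bases reach
the joint minor count of 4 (stray sub-threshold bases are treated as
sequencing noise; three or more above-threshold bases ⇒ the site is
dropped entirely as multi-allelic, not reduced to its top two). The
minor allele is defined on the joint counts so per-population
frequencies are comparable; frequencies use the two retained alleles'
counts. Rejections are tallied by reason.

**Detection-weighted Watterson**. The classical θ_W = S/a₁ undercounts
segregating sites in pools because a site is only *detected* when
binomial read sampling yields ≥ b minor reads. The denominator is
therefore the expected detected-sites-per-unit-θ,
D(n,C,b) = Σ_{i<n} (1/i)·P(b ≤ Bin(C, i/n) ≤ C−b), evaluated per site
at its own coverage and summed over valid exonic positions; θ̂ per site
= S/ΣD. Properties verified: exact enumeration at (n=4, C=2, b=1) gives
D = 0.75; the C→∞, b=1 limit recovers a₁; Monte Carlo at 10⁶ sites
agrees within 1%; doubling coverage moves θ̂ by < 2% on error-free
paired simulations; seed-averaged recovery at study conditions is
biased +2% (residual sequencing-error false positives), within the 5%
acceptance band. A gene enters the genome-wide unweighted mean only if
≥ 50% of its exonic *positions* are validly covered in every population
— a fraction of positions, not of SNPs, because "fraction of SNPs"
would be circular (SNP status depends on the same thresholds); the
basis is exposed as a parameter.

**Pooled Tajima's D** is labelled approximate by construction: π̂ per
site applies n/(n−1) and C/(C−1) corrections at sites passing the 13×
(= n/3) coverage floor, θ̂ uses the detection weights, and the classical
variance constants are evaluated at an effective sample size
min(n, mean valid coverage) because no pooled variance formula is
available. Sub-threshold minor reads contribute zero π (they are
indistinguishable from error). Consequences, measured on neutral data
(2,000 genes): the per-gene mean D is ≈ −0.11, not 0 — detection loss
of singleton π mass biases D slightly negative — which is why the
neutral-centering check uses the band |mean D| < 0.15 rather than
exact centring. Rare-variant-enriched spectra drive the mean strongly
negative, matching the sign behaviour the statistic exists to capture.

**Pooled F_ST**: per SNP, (H_T − H̄_S)/H_T with H_T at the mean of the
two pool frequencies. Two combinations over SNPs are provided. The
per-SNP mean (`combine="mean"`, the convention of the sliding-window
pool tools) sits systematically *below* the generating F when rare
variants dominate — each low-frequency SNP contributes a near-zero
ratio — measured 0.038 at F = 0.05 under the 1/p spectrum; this is the
mechanism by which high-coverage Pool-Seq deflates F_ST relative to
microsatellites. The Weir-style ratio of sums (`combine="ratio_of_sums"`)
recovers F within ±0.01 (measured 0.047 at F = 0.05; the residual gap
is the two-deme H_T bias partially cancelled by read/pool sampling
noise). Recovery checks target the ratio-of-sums combination because
only it has the closed-form expectation; both values are reported.

## Comparison battery

Correlations (Pearson; Spearman with midranks), paired t-tests
(df = n−1; zero-variance differences flagged, never silently p = 0),
pairwise Wilcoxon signed-rank on per-locus H_e (zero differences
dropped, exact null for ≤ 25 pairs, Bonferroni over all population
pairs), Mantel tests (Pearson on lower triangles, joint row/column
permutation of the second matrix, one-sided positive by default as in
all emulated usages, 1001 permutations, seeded), and the Tajima's-D
against-zero test implemented literally as the emulated workflow
describes — a Welch two-sample t-test against an equal-size
pseudo-sample from Normal(0, sd(observed)) with a recorded seed — with
the conventional one-sample t-test behind `one_sample=True`. The
pseudo-sample size is taken equal to the observed sample (the source
procedure leaves it unstated) and is recorded in the result.

## Down-sampling

Per replicate one random permutation of the (chrom, pos)-sorted SNP
panel is drawn and its prefixes provide the subsamples for every k —
each prefix of a uniform permutation is exactly a uniform
without-replacement subsample of its size, so per-k distributions are
exact while the cost drops by orders of magnitude; replicates are
independent, and the same SNP indices apply to all populations within a
replicate. CIs are 2.5–97.5 percentiles of replicate means
(distribution-free, matching the visual bands such analyses plot). The
threshold criterion is simultaneous over populations (a per-population
breakdown is also emitted); ranking uses non-overlapping CIs with pairs
within 0.0005 in full-data H_e exempted as genuinely tied (the
reference table prints H_e to three decimals, and two populations tie
at 0.154). Measured on the default synthetic panel (≈ 4 × 10⁴ retained
SNPs): CI half-width ∝ 1/√k with R² > 0.995; k(±0.01) ≈ 1,100 against
a CLT prediction (1.96 s/0.01)² ≈ 1,140; k(±0.005) ≈ 4,100. The
published analysis reports 1,000 / 4,000 / 93,000 and 300,000 for
ranking; the first two scales reproduce here, while the ±0.001 and
ranking panel sizes depend on the unpublished empirical per-SNP H_e
distribution and total panel size (2 × 10⁶ SNPs) and are not
reproducible at this scale.

## Problem sizes and runtime

Recovery experiments run at: 2,000 genes × 500 bp × 3 populations × 20
seeds (Watterson, ≈ 1 min), 5 × 10⁴ SNPs × 9 populations × 20 seeds
(F_ST/H_e, ≈ 1 min), 200 diploids × 20 seeds (EM), 10⁶ sites (detection
Monte Carlo), 1,000 replicates over the grid to 4 × 10⁴ (down-sampling),
and 100 seeded runs of the 19-locus battery. The full acceptance script
completes in a few minutes on one CPU.

## Known limitations

- The pooled Tajima's D is approximate (see above); its values are for
  sign and ranking, not absolute calibration.
- The per-SNP-mean pooled F_ST is spectrum-dependent by design; compare
  values only between identically filtered panels.
- The generator has no linkage, no demographic trajectories (SFS skew
  stands in), no genotyping error besides null alleles, and
  Balding–Nichols drift rather than an explicit coalescent; passing
  recovery tests shows estimator correctness under this model, not
  robustness to demographic misspecification.
- The 19-locus variance-bias battery sits at the edge of its nominal
  acceptance bound (fraction of runs without any Bonferroni-significant
  Wilcoxon pair ≈ 0.77–0.80, Monte Carlo sd ≈ 0.04 at 100 runs): the
  qualitative phenomenon is robust, the fraction itself is boundary.
- GenePop population labels are recovered from shared `name_` prefixes
  of individual ids; files without that convention get `pop1…popK`.
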