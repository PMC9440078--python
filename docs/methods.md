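# Methods

This note documents the statistical models, the parameter choices and their
rationale, what the synthetic-data generator does and does not emulate, and
the numerical decisions a maintainer would want to know about.

## Genotype model

Genotypes are unphased alt-allele dosages in {0, 1, 2} with a dedicated
missing sentinel; `0/1` and `1/0` collapse to dosage 1 because every
statistic in the package (heterozygosity, HWE, IBS/IBD moments, homozygosity
runs) is phase-free. Coordinates are VCF-style 1-based inclusive; variant
order is (contig, position) with contig order taken from the VCF header.
Round-tripping a matrix through `write_vcf`/`read_vcf` is exact (dosages,
positions, alleles, QUAL), which the tests rely on.

## Variant QC

Sites are removed when QUAL ≤ 30 (bounds inclusive on the removal side),
exact-test HWE *P* ≤ 10⁻⁵, MAF ≤ 0.05, or (by default) any call is missing.
Removals are attributed to the first failing criterion in the fixed order
biallelic → qual → call rate → HWE → MAF so that report counts are
deterministic; the order is a reporting convention only — the surviving set
is order-independent.

The HWE test is the genotype-exact conditional test: given the observed
allele counts, the probability of each compatible heterozygote count is
evaluated (log-gamma arithmetic, normalized in a numerically safe way) and
the p-value sums the configurations no more probable than the observed one
(standard, non-mid-p form). An inclusion tolerance of 1 + 10⁻⁹ on the
probability comparison absorbs float noise on exactly tied configurations;
the test suite checks agreement with an exact rational-arithmetic
enumeration oracle to 10⁻¹² for every configuration with up to 50 diploids.

LD pruning reproduces the windowed pairwise scheme: windows of `window_snps`
retained variants advancing by `step_snps` per contig (defaults 25/5 at
r² > 0.5; the stringent regime 200/20 at r² > 0.2 defines the marker subset
for the bottleneck test). r² is the squared Pearson correlation of dosage
vectors (composite LD — phase-free and deterministic). Within a window the
highest-r² offending pair is resolved first and its lower-MAF member removed
(later position on ties); passes repeat to a fixpoint so no scheduled window
on the survivor list retains a pair above the threshold. Zero-variance sites
carry no LD information and are never removed for LD. A threshold of exactly
1.0 is internally capped just below 1 so that only exactly collinear sites
are removed there.

## Diversity and the bottleneck test

Per site, H_O is the heterozygote proportion among called genotypes and
H_E = 2p(1−p) from the cohort allele frequency. Windowed nucleotide
diversity uses the unbiased per-site heterozygosity over 2n chromosomes,
π = Σ 2·c_ref·c_alt/(n_chr(n_chr−1)) per window base pair, windows anchored
at position 1 and all normalized by the nominal width (including the final
partial window).

The bottleneck test aggregates per-locus heterozygosity excess
Δ_l = H_O,l − Ĥ_E,l into T2 = L^(−1/2) Σ Δ_l/σ_l with a one-sided 5%
rejection at T2 ≥ 1.645. Two numerical points matter:

1. **Unbiased Ĥ_E.** 2p̂(1−p̂) underestimates H_E by a factor (2n−1)/(2n)
   when p̂ comes from the same sample; Ĥ_E is multiplied by 2n/(2n−1) so that
   E[Δ_l] = 0 exactly under HWE. Without this, the per-locus bias is tiny
   (≈ H_E/2n) but T2 sums it across thousands of loci into a spurious
   rejection.
2. **The null SD of Δ, not of H_O.** The errors of H_O and Ĥ_E are strongly
   positively correlated (both are functions of the same genotype counts).
   By the delta method, under HWE

       Var(H_O − Ĥ_E) ≈ H_E² / n,

   i.e. σ_l = H_E,l/√n — noticeably smaller than the binomial SD of H_O
   alone, √(H_E(1−H_E)/n). The package defaults to the delta-method σ_l
   (`sigma="analytic"`); the binomial form and a Monte-Carlo resampling form
   are available for sensitivity analysis (`sigma="binomial"|"mc"`). With
   the analytic default the test is correctly calibrated: over 2000 null
   replicates of 5000 HWE loci at n = 71, T2 has mean ≈ 0, SD ≈ 1 and type-I
   error ≈ 0.05 at the 1.645 cut (the acceptance suite re-verifies this);
   the binomial form is markedly conservative (SD ≈ 0.77).

An alternative aggregation that multiplies Δ_l by √σ_l instead of dividing
(`form="sqrt"`) is provided for comparison with sources that print the
statistic that way; division is the default because only it yields a
unit-variance Z-score. Loci fixed in the sample (σ_l = 0) are excluded from
L. Cohort summaries report mean ± sample SD (n−1 denominator).

## Relatedness

Observed genome-wide IBS-state proportions are inverted to IBD probabilities
by the method of moments. Expected IBS-given-IBD terms use allele
frequencies estimated from the cohort itself with the standard finite-sample
corrections (each product of k independent allele draws replaced by its
unbiased counterpart based on the observed allele count); at n ≈ 71 these
corrections are what keep PI-HAT from being inflated. Negative moment
estimates are truncated at zero and the triple renormalized to sum to one,
so "unrelated" is PI-HAT exactly 0 after bounding. Sites are treated as
independent — feed the pruned marker set. Pairs with fewer than 100 jointly
informative sites are flagged low-confidence. Category portions are rounded
half-up to two decimals.

Recovery, verified on gene-dropped pedigrees with cohort-estimated
frequencies at 10,000 markers: parent–offspring mean PI-HAT within 0.05 of
0.5, half-sibs within 0.05 of 0.25, unrelated founders ≤ 0.02 (the residual
positive mean on truly unrelated pairs is the truncation bias of the bounded
estimator and shrinks with marker count).

## Runs of homozygosity and inbreeding

The caller scans windows of 25 SNPs in one-SNP steps; a window is a hit when
it has at most `window_max_het` heterozygous (default 1, with 0 as the
stricter variant) and at most 5 missing calls. A SNP is eligible when ≥ 5%
of the complete windows containing it are hits and its own call is not
heterozygous; missing calls can sit inside runs but count toward the window
limits. Maximal runs of eligible SNPs are split at inter-SNP gaps > 1000 kb
and kept when they have ≥ 25 SNPs, span ≥ 500 kb and average ≤ 25 kb per
SNP. Segments are SNP-anchored (first to last SNP, inclusive). Contigs with
fewer SNPs than one window yield no segments. Tightening any single
condition can only shrink the called set (tested as a monotonicity
property).

Length bins are right-closed at 1.0/1.5/2.0/2.5 Mb with the first bin closed
at 0.5 Mb so the minimum-length segment has a bin; bin totals partition each
sample's total ROH length, and per-pack values are means of per-sample
totals.

F_HOM uses the unbiased expected homozygosity (the same 2n/(2n−1) factor as
above) so its cohort average is centered on zero under HWE; it goes negative
under heterozygote excess. F_ROH divides total ROH length by the SNP-covered
genome, L_total = Σ_contigs (last SNP − first SNP + 1) — a definition, not
an estimate of assembly length.

## Population structure

The GRM is G = (1/M) Σ_i (g_i − 2p_i)(g_i − 2p_i)ᵀ / (2p_i(1−p_i)) over
polymorphic sites with cohort frequencies (missing dosages contribute zero
after standardization, i.e. mean imputation). PCA is the eigendecomposition
of G; scores are eigenvectors scaled by √λ, explained fractions are
λ_k/Σ(positive λ), and each eigenvector's sign is fixed by making its
largest-magnitude loading positive so output is deterministic across
platforms.

## The synthetic cohort generator

The generator is the package's ground truth, built to contain exactly the
structure the analysis is supposed to detect, at a reduced scale chosen once:
**five 50-Mb contigs (≈10% of a canid genome) carrying 20,000 SNPs**
(~12.5 kb mean spacing — inside the 25 kb/SNP ROH density condition),
founder MAF ~ Uniform(0.05, 0.5), Haldane recombination at 1 cM/Mb.

* **Bottleneck.** Site frequencies drift by Wright–Fisher binomial
  resampling for `generations` rounds at the post-bottleneck size
  (default preset: 5 generations at 10 diploids), conditioned on staying
  polymorphic — so rare alleles are preferentially lost, exactly as in a
  real bottleneck. The final cohort's paternal and maternal alleles are then
  drawn from two finite breeding pools of 2·post_size alleles each. Because
  the two pools differ by sampling, progeny heterozygosity exceeds the
  Hardy–Weinberg expectation computed from cohort-estimated frequencies by
  ≈ H_E/(2·post_size) — the heterozygote excess is a mechanical property of
  the genotypes, not an injected statistic. This is a deliberate
  simplification of mutation–drift disequilibrium: it reproduces the
  per-site Δ > 0 signature and its magnitude scale, not coalescent gene
  genealogies, so quantitative T2 values from the simulator do not transfer
  to real cohorts.
* **Pedigree.** Offspring haplotypes are crossover mosaics of parental
  haplotypes (Poisson crossover counts at the map length, uniform
  positions), with founder-haplotype ancestry tracked per SNP. Expected
  PI-HAT comes from kinship path counting; realized autozygous tracts are
  read off ancestry equality, so offspring of consanguineous matings carry
  genuine recombination-shaped ROH.
* **Planted ROH.** Autozygosity can also be forced directly (one haplotype
  copied over the other across an interval, truth recorded) — used both for
  long "recent-inbreeding" tracts and for the study-shaped preset's short
  ancient-consanguinity burden (2 tracts of 0.55–1.0 Mb per sample,
  ≈ 0.5% of the genome, matching the F_ROH scale of a bottlenecked but
  outbred cohort; a much heavier burden would mechanically cancel the
  heterozygote excess, which is not what such cohorts show).
* **The study-shaped preset** (`study_cohort_config`): 71 samples in 24 packs
  across three regions (sample shares ≈ 13/21/37), the severe bottleneck,
  and three matings whose second parent is outside the cohort, so the
  emitted cohort contains exactly three first-degree pairs.

What the generator does **not** emulate: coalescent LD (background LD for
pruning tests is created by duplicating/jittering columns), mutation,
selection, realistic canid recombination maps, genotyping error and missing
data patterns, and platform batch effects. Passing tests therefore
demonstrate correctness of the estimators under their stated models, not
robustness to those real-data complications.

Everything is reproducible bit-for-bit under a fixed seed (byte-identical
emitted files).

## Problem sizes and numerical conventions

Default analysis/simulation sizes were chosen once to make every property
measurable with comfortable statistical margins: 20,000 markers for
ROH/bottleneck work, 10,000 for relatedness recovery, 2000 × 5000-locus
replicates for null calibration, 200 replicates for bottleneck power,
full-sib F_ROH assessed as the mean over offspring of five independent
families (per-offspring realized autozygosity has SD ≈ 0.13 on a 2.5-Morgan
genome, so single offspring are individually noisy). Ties and degenerate
inputs: monomorphic sites are skipped (with counts) wherever a statistic is
undefined on them; all-missing sites raise explicit undefined-statistic
errors; the T2 rejection comparison carries a 10⁻⁹ slack so a statistic
landing exactly on 1.645 rejects despite float rounding.

## Known limitations

* The IBD moment estimator assumes marker independence; residual LD inflates
  pair-level variance (visible as boundary misclassifications near the 0.50
  category cut).
* The ROH caller is the windowed genotype scan, not an HMM; extremely sparse
  or extremely dense marker sets shift its effective sensitivity through the
  density and window conditions.
* F_ROH depends on the marker-covered genome definition; comparisons across
  datasets should use the same definition.
* The bottleneck test's calibration is exact under HWE sampling of
  independent loci; strong LD between loci would inflate |T2| (use the
  stringently pruned subset).
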