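# Methods

This note documents the models, conventions and design choices behind
loadscape, in the order the pipeline runs them.

## Genotype representation and filtering

Genotypes are biallelic diploid dosages {0, 1, 2} with −1 for missing
calls; positions are 1-based (VCF convention) externally and all internal
interval logic is done on 1-based inclusive coordinates.  Site filtering
retains sites that are biallelic among observed genotypes, have missing
rate ≤ 20% (default) and minor-allele frequency ≥ `min_maf` computed on
called alleles only.  Filtering is idempotent.

LD pruning follows the plink `--indep-pairwise` dialect on dosage
correlation: windows of 50 sites advanced by 10, and while any retained
pair in a window exceeds r² = 0.2 the lower-MAF member of the worst pair is
dropped (ties: the later coordinate), which makes the procedure
deterministic.  Exact upstream depth/quality filters depend on the variant
caller and are out of scope; QUAL/FORMAT-DP screening can be applied when
reading a VCF that carries them.

## Windowed statistics

π, D_XY and Hudson's F_ST use allele-count component sums per site and
ratio-of-sums aggregation over non-overlapping 100-kb windows anchored at
position 1 per chromosome (trailing partial windows keep their true span).
Sites contribute exactly the called alleles they carry: a site with fewer
than two called alleles contributes nothing to π, and a fully missing site
changes no statistic.  Hudson's estimator is F_ST = 1 − H_w/H_b with H_w
the mean of the two within-population π values and H_b = D_XY, each a
ratio of window sums; slightly negative values are reported as computed
(an optional clamp exists for plotting only).  Under the Balding–Nichols
model this estimator is unbiased for the generating differentiation
parameter, which the tests exploit.

Tajima's D uses only sites with complete genotypes in the window (the
cohort haplotype count n is then unambiguous) and requires at least three
segregating sites; fewer yields an explicit undefined (NaN) marker, never
a silent zero.  The selection-scan cutoff is the one-sided standard-normal
quantile, reported rounded to 4 decimals (99% → 2.3263).

## Polarization and mutation load

The ancestral allele at a site is the allele homozygous in more than 50%
of genotyped individuals; the majority is computed over genotyped
individuals so the rule degrades gracefully under missingness (for a
complete 154-individual cohort it reduces to the familiar ">77
individuals" count).  Sites with no such majority are excluded, as are
sites whose inferred ancestral allele is not the reference allele — if the
reference genome itself carries the derived allele, het/hom orientation
from dosage codes cannot be trusted.  After polarization the ancestral
allele always equals the reference, so dosage 1 = derived heterozygote and
dosage 2 = derived homozygote directly.

Grantham distances are computed from the published residue properties
(composition, polarity, molecular volume) with α = 1.833, β = 0.1018,
γ = 0.000399 and ρ normalizing the mean over the 190 residue pairs to 100,
then rounded to integers.  This reproduces the canonical anchor values
(identity 0, Leu–Ile 5, Cys–Trp 215); the formula-generated table packaged
with the code is authoritative, since the historically printed matrix
contains a handful of ±1 rounding irregularities that no single scaling
constant reproduces.  The minimum distance between distinct residues is 5,
so the TOL lower bound is vacuous; a "missense" record with identical
residues is treated as an annotation error and excluded.

Load statistics are defined in the README.  The masked/realized
denominator counts SYN derived *alleles* (2·hom + het) by default, with
homozygous deleterious loci weighted 2 in the realized numerator — the
per-locus weighting "two per homozygous locus and one per heterozygous
locus" applied consistently on both sides of the ratio.  Because locus
counting is an equally defensible reading, `count_mode="loci"` implements
it (unit weights, SYN locus denominator).  Individuals' missing genotypes
at polarized sites enter neither numerators nor denominators.  Population
load is the mean over member individuals (not the median).

## ROH and inbreeding

With a zero-heterozygote allowance, the 50-SNP scanning window is exactly
equivalent to calling maximal runs of consecutive non-heterozygous
genotyped SNPs, which is how the scan is implemented.  Missing genotypes
inside a run neither break it nor count toward its SNP support; a gap
larger than 1 Mb between consecutive genotyped SNPs does break it.
Segments need ≥10 kb span and ≥50 supporting homozygous SNPs, then class
as short [10, 100) kb, medium [100, 200) kb, long ≥ 200 kb.  The gap and
SNP-support defaults are conventional ROH-caller settings, exposed as
parameters.  F_ROH divides summed segment length by the genome length from
the chromosome-sizes table (not the SNP-covered span).  Note that a
≥10-kb segment needs ≥5 SNPs/kb to reach 50 supporting SNPs; at sparser
marker densities the effective minimum segment length is set by the SNP
support, as with any count-thresholded caller.

F_IS follows plink `--het`: F = (O_hom − E_hom)/(N_used − E_hom) with
E_hom summed over the individual's called sites from cohort allele
frequencies with the 2n/(2n−1) small-sample correction.  In structured
cohorts F_IS absorbs the Wahlund effect and overestimates individual
inbreeding relative to F_ROH; the two remain positively rank-correlated,
which is asserted as a property.

## Gradient forest and genomic offset

Per locus a bagged ensemble of `n_trees` = 500 regression trees
(scikit-learn, `max_features` = 1/3, `min_samples_leaf` = 2 — sized for
population-level fits with ~13 observations) predicts population allele
frequencies from climate.  Locus fit quality is out-of-bag R², truncated
at zero so unpredictable loci contribute nothing.  Every split's impurity
reduction accrues to its variable at the split threshold; per locus the
accrued mass is normalized to 1, weighted by the locus R², and averaged
over loci, so each variable's total importance is on the scale of mean
per-locus predictability.  Binning is 101 equal-width bins over the
training range; the cumulative curve is anchored at 0 at the range minimum
and evaluated piecewise-linearly, with values outside the training range
clamped to the ends.  This impurity-reduction importance is a deliberate
simplification of the reference implementation's conditional-permutation
importance; it preserves variable ranking and the turnover geometry that
the offset computation consumes.

Redundant climate variables are removed greedily before the final fits:
among any pair with |Spearman R| > 0.7 the variable with lower preliminary
GF importance is dropped, repeating until no pair exceeds the threshold.
The preliminary ("screening") forest is fit on the loci with the highest
across-population frequency variance — the most informative subset — so
the causal gradient, not a drift artifact, decides which member of a
correlated pair survives.

Offsets are Euclidean distances in turnover space between current and
future climate, computed per cell and per scenario and then averaged over
the four SSP scenarios (averaging offsets, not climates, matches the
intended interpretation of scenario means and is not equivalent to
offsetting the mean climate).  Population offsets average the grid cells
within 20 km (haversine) of the population coordinate.

Adaptive loci come from a permutation RDA: the centered population ×
locus frequency matrix is regressed on standardized climate variables, the
fitted values are decomposed by SVD, and each locus is scored by its
squared loading norm on the first three constrained axes; the empirical
p-value is (1 + #{permuted ≥ observed})/(n_perm + 1) under row permutation
of the climate table with n_perm = 999, flagging loci at p ≤ 0.05.  The
"first three axes" convention is implemented as scoring on three
constrained RDA axes (the alternative reading — three climate PCs as
predictors — is not used).  Neutral loci are a uniform, seeded sample of
intergenic-annotated loci, sized to match the adaptive set.  In strongly
structured cohorts the permutation null does not account for shared
drift–geography confounding, so the flagged fraction can exceed the
nominal level on structured neutral loci; calibration at the nominal α
holds for exchangeable (unstructured) frequencies and is asserted under
those conditions.

## Synthetic cohorts

The generator emulates the study design the analysis assumes: 13
populations (154 individuals) in two lineages, five of them designated
edge populations with smaller sample sizes.  Allele frequencies follow a
hierarchical Balding–Nichols model: lineage frequencies diverge from the
ancestral frequency with `fst_target` = 0.35, then populations drift
within lineages (0.04 west, 0.10 east, +0.12 for edge populations).
Functional classes mix as SYN 15%, TOL 10%, DEL 2%, LOF 1%, intergenic
60%, other 12%, with derived-frequency Beta priors of mean 0.10 (SYN),
0.05 (TOL) and 0.02 (DEL/LOF) mimicking purifying selection without
forward simulation.  Autozygosity is injected by overwriting per-individual
tracts (core: 150 + 250 kb; edge: 2 × 100, 2 × 200, 2 × 300 kb) as
homozygous runs — sufficient to exercise ROH detection and F_ROH recovery,
though not a pedigree model.  Adaptive loci (60 by default, hosted on
"other"-class sites so they never contaminate the intergenic neutral pool)
get population frequencies from a logistic cline on the standardized
driving variable (BIO1, slope 4) plus Gaussian noise (sd 0.05).

Climate is a set of smooth deterministic bioclim-style fields evaluated on
a regular lat/lon lattice (default cell 1/24° ≈ 4.6 km), so population
profiles and grid cells are mutually consistent; several variables are
strongly collinear by construction to exercise redundancy removal.  Four
future scenarios apply additive displacements of increasing severity
(1.2/2.0/3.0/4.2 °C at the range core) amplified up to ~3× in Gaussian
bumps around the edge populations — the generator's encoding of "edge
populations face larger climate displacement".  The default genome is
8 × 6 Mb with 50,000 SNPs (~1 SNP/kb), a deliberate scale-down that keeps
the full pipeline within minutes on one CPU while preserving every
statistical property under test; a real cohort would be ~3 orders of
magnitude larger in sites but identical in code path.

What the generator does not emulate: linkage disequilibrium decay along
chromosomes (sites are exchangeable given frequencies), realistic site
frequency spectra from demography (a dedicated 1/p-spectrum sampler exists
for Tajima's D calibration only), gene flow, phased haplotypes, and
selection acting jointly on linked sites.  Passing tests therefore
demonstrate correctness of the estimators and the recovery machinery, not
realism of any particular demographic inference.

For Tajima's D calibration, single-population genotypes are drawn with
site frequencies from the equilibrium neutral density ∝ 1/p (truncated at
1/(20·n)), under which the pairwise and Watterson estimators share the
same expectation and the mean D over many windows is near zero.

## Determinism and numerical conventions

All stochastic steps take explicit seeds; a fixed seed yields bit-identical
cohorts, models and pipeline outputs (asserted by rerun).  Undefined
statistics are NaN, never zero.  Dosage r² returns 0 for constant columns.
RDA guards against rank-deficient climate designs by naming a collinear
pair.  The pipeline caps the loci fed to the gradient forest (150 per SNP
set, screening on 200) — the forests are fit per locus, so this bounds run
time linearly while leaving the RDA scan exhaustive; the caps are
configuration parameters.

## Known limitations

- The GF importance is impurity-based, not conditional-permutation; with
  heavily collinear predictors importance can spread among survivors of
  the redundancy filter.
- F_ROH recovery is quoted for marker densities that give injected tracts
  ≥50 SNPs; in heavily drifted populations genuine background homozygous
  runs add to F_ROH beyond injected truth, which is correct behavior of
  the caller but must be kept in mind when comparing against injected
  fractions alone.
- The RDA permutation null assumes exchangeable populations; structured
  cohorts inflate the flagged fraction relative to α (see above).
- Load statistics assume the annotation's effect classes are correct and
  independent across sites; no attempt is made to model dominance or
  epistasis.
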