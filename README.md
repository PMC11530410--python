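# loadscape

Genomic-vulnerability analysis for structured diploid cohorts: mutation-load
decomposition, runs of homozygosity and inbreeding, windowed
diversity/divergence statistics, and gradient-forest genomic offset under
future climate scenarios.

The package is aimed at conservation and landscape genomicists working with
whole-genome resequencing of non-model species — typically a few hundred
individuals from a dozen populations spanning two diverged lineages, as in
relict tree species of subtropical East Asia.  It takes a multi-sample VCF,
a variant-effect annotation table, a population map and gridded climate
tables, and answers three questions: how much deleterious variation does
each population carry (and how much of it is expressed), how inbred is each
individual, and how far must each population's genotype–environment
association shift under projected climates.

A fully synthetic cohort generator with known ground truth ships as a
first-class module, so the entire pipeline can be exercised and validated
without any external downloads.

## The statistics at the core

**Mutation load.** Sites are polarized by cohort majority: the allele
homozygous in >50% of genotyped individuals is ancestral; sites whose
inferred ancestral allele disagrees with the reference are excluded as
potential reference bias.  Derived alleles are classed by effect:
synonymous (SYN), missense with Grantham distance 5–150 (TOL, tolerated),
missense with Grantham distance >150 (DEL, deleterious), and stop-gain /
splice-disruption (LOF).  Per individual, with n_hom and n_het the derived
homozygote and heterozygote counts:

    homozygosity load (per class) = 2·n_hom / (2·n_hom + n_het)
    masked load   = [n_het(DEL) + n_het(LOF)] / SYN derived alleles
    realized load = 2·[n_hom(DEL) + n_hom(LOF)] / SYN derived alleles

The Grantham distance combines residue composition, polarity and molecular
volume: D_ij = ρ·[α(c_i−c_j)² + β(p_i−p_j)² + γ(v_i−v_j)²]^½ with the
published constants and ρ normalizing the 190-pair mean to 100.

**Inbreeding.** ROHs are maximal runs of consecutive non-heterozygous
genotyped SNPs (50-SNP scanning window, zero heterozygotes, ≥10 kb, classed
short/medium/long at 100 kb and 200 kb).  F_ROH is the summed ROH length
over the genome length; F_IS is the method-of-moments coefficient
(O_hom − E_hom)/(N − E_hom) from cohort allele frequencies.

**Diversity and divergence.** π, D_XY and Hudson's F_ST are computed as
ratios of window sums with missing-data-aware denominators (the pixy
convention), in non-overlapping 100-kb windows; Tajima's D uses the
standard 1989 constants on complete-genotype sites.  The selection-scan
significance threshold is the one-sided 99% normal quantile, 2.3263.

**Genomic offset.** Per locus, a bagged regression-tree ensemble (500
trees) predicts population allele frequencies from climate; split-impurity
importance, weighted by out-of-bag R², accumulates along each climate
variable into a monotone cumulative "allelic turnover" function.  The
genomic offset of a grid cell is the Euclidean distance between its current
and future climate after mapping both through these functions, averaged
over four SSP scenarios; population offsets average the cells within 20 km.
Adaptive loci are flagged by permutation RDA (999 permutations, scores on
the first three constrained axes), neutral loci are drawn from intergenic
annotations.

## Worked example

```python
from loadscape.simulate import SimulationConfig, simulate_cohort
from loadscape import roh, popgen
from loadscape.load import polarize, classify_sites, compute_load, population_load

config = SimulationConfig(
    n_sites=4000,
    chrom_lengths={"chr1": 2_000_000, "chr2": 2_000_000},
    seed=7,
)
cohort = simulate_cohort(config)

loads = compute_load(
    cohort.matrix, polarize(cohort.matrix), classify_sites(cohort.annotations)
)
pop_loads = population_load(loads, cohort.popmap)
print(pop_loads[["population", "masked_load", "realized_load"]].round(4).head(4))

segments = roh.detect_roh_cohort(cohort.matrix)
report = roh.inbreeding_report(
    cohort.matrix, segments, sum(cohort.chrom_sizes.values())
)
r, p = popgen.landscape_correlation(report["f_roh"], report["f_is"])
print(f"F_ROH ~ F_IS Spearman R = {r:.2f} (p = {p:.2e})")
```

prints

```
population  masked_load  realized_load
        DH       0.0040         0.0000
        ES       0.0079         0.0568
        LH       0.0088         0.0000
        LP       0.0546         0.0431
F_ROH ~ F_IS Spearman R = 0.63 (p = 1.05e-18)
```

Masked load is the deleterious variation hidden in heterozygotes relative
to the synonymous background; realized load is the expressed, homozygous
part.  ES is an edge population simulated with stronger drift and more
autozygous tracts, and its realized load and F_ROH are correspondingly
elevated; the positive F_ROH–F_IS correlation shows the two inbreeding
coefficients agree in ranking individuals.

The same analysis runs from the shell on written files:

```sh
loadscape simulate --out-dir cohort/ --seed 1
loadscape all --config run.yaml        # filter -> load -> ROH -> stats -> offset
```

where `run.yaml` lists the input paths and any stage parameters
(`max_missing_rate`, `window_size`, `n_trees`, `radius_km`, ...).  Each run
writes per-stage TSVs, a per-population summary with pairwise Spearman
correlations, and a JSON manifest with every resolved parameter, seed and
input checksum.

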