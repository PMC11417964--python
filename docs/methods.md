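# Methods

`consgen` implements a conservation-genomics workflow for fragmented,
endangered plant populations: characterize diversity, inbreeding and genetic
load from resequencing genotypes; find climate-associated loci; project
genomic offset under future climates; and model niche-suitability change.
Every stage can be exercised end to end on synthetic data with recorded
ground truth, which is what the test suite and the acceptance script do.

## Synthetic data generator (`consgen.syndata`)

The generator emulates a range-wide resequencing survey of a long-lived
tree: by default 16 populations of ~10 diploids, 13 chromosomes, ~6.5x mean
depth, a 10-year generation time, and a handful of bioclim-style climate
fields on a grid. Site counts and chromosome lengths are desk-scale (10^3–10^4
sites over tens of Mb) so a full run takes minutes, not days.

**Divergence.** Population allele frequencies follow the Balding–Nichols
model: ancestral frequency p ~ U(0.05, 0.95) (the support avoids sites that
would be discarded wholesale by the MAF filter), and each population draws
from Beta(p(1−F)/F, (1−p)(1−F)/F), whose variance F·p(1−p) makes F the FST
parameter. F = 0 copies the ancestral frequency exactly. Genotypes are
Binomial(2, freq) per individual (HWE within populations).

**Sequencing artifacts.** Depth is Poisson(6.5) per genotype. Genotype
quality is a mixture — 10% of genotypes U[10, 60), the rest U[30, 60) — so
the DP/GQ recoding rule of the filter ladder fires on a realistic ~10% of
genotypes. An all-low-quality draw (GQ ~ U[10, 60) everywhere) would recode
>20% of calls and push nearly every site past the 20% missing-rate rule,
leaving an empty dataset; the mixture keeps every filter branch exercised
without destroying the data.

**Inbreeding.** Runs of homozygosity are planted as explicit tracts: inside
each tract the individual keeps one haplotype sampled from its own two
alleles at every site, so heterozygotes vanish while allele frequencies are
approximately preserved. By default every individual of the first population
carries one 2-Mb tract.

**Deleterious variation.** Sites are annotated intergenic/intron/CDS, CDS
sites as 0-fold or 4-fold degenerate; 0-fold sites carry a SIFT-like score.
Deleterious sites (score < 0.05) get low ancestral derived frequencies
(U(0.02, 0.15)), reflecting selection keeping damaging alleles rare.
Per-class heterozygosity is additionally shrunk toward fixation
(intergenic 1.0 > fold4 0.8 > intron 0.6 > cds 0.45 > fold0 0.3), the
purifying-selection footprint; note this shrinkage slightly raises realized
FST at constrained sites above the nominal F, so the FST-recovery guarantee
applies to the unshrunk Balding–Nichols frequencies.

**Climate links.** Linked sites replace their population frequencies with
expit(logit(p) + b·z_v), z_v the standardized variable (default slope b = 2,
25 sites on the first variable). Their ancestral frequencies are drawn low,
U(0.03, 0.12): the climate-favored derived allele is globally rare and
frequent only in the warmest populations — range-edge local adaptation.
This matters for the offset stage (below).

**Landscape.** Climate fields are Gaussian-smoothed white noise,
standardized per field. Suitability is logistic with coefficients (−2, −1,
0, …): a cool-adapted species whose favorable envelope shrinks when the
first (temperature-like) field rises. Occurrences are sampled with
probability proportional to suitability. Future grids add per-GCM shifts of
0.4/0.5/0.6 SD to the temperature-like field, amplified by
(1 + 0.5·current value) — valley floors warm more than ridgetops. Shifts of
~0.5 SD move the envelope substantially while keeping most locations' future
climates inside the gradient-forest calibration range; with much larger
shifts the transform clamps at the training-range edge and offsets at the
warm margin collapse to zero, inverting the altitude pattern. Altitude is
1000 − 400·(temperature field) + noise, i.e. strongly anti-correlated with
temperature.

**What the generator does not emulate:** linkage disequilibrium beyond
planted tracts (sites are exchangeable draws, so LD-decay curves on
synthetic data show only the small-sample floor), recombination maps,
coalescent genealogies (the site-frequency spectrum is not the neutral 1/i
spectrum — estimator agreement tests that need neutrality use msprime
simulations instead), sequencing reads, reference bias, or spatially
autocorrelated sampling. Passing tests therefore demonstrate correctness of
the estimators and detectors under known truth, not performance on real
LD-structured data.

## Filter ladder (`consgen.variants`)

Six rules in fixed order: (i) site mean coverage within [0.5x, 2x] of the
genome-wide mean (computed from the input itself); (ii) excluded contigs;
(iii) genotypes with DP < 3 or GQ < 20 recoded missing — sites left with no
called genotype are dropped here and counted under this rule; (iv)
biallelic SNPs only; (v) missing rate ≤ 20% ("dataset 1"); (vi) MAF ≥ 0.05
over non-missing haplotypes ("dataset 2"). The report satisfies
removed + surviving = input. Order matters and is tested: recoding before
the missing-rate rule changes the survivor set. LD pruning is greedy
sliding-window r² (window 50 SNPs, step 10, r² 0.2 — common practice;
exposed), and distance thinning keeps the first SNP per 100-kb window.

## Diversity and differentiation (`consgen.popgen`)

Per-site π = 2c(n−c)/(n(n−1)) over non-missing haplotypes; θπ sums π over a
region class and divides by its callable length, which is an explicit input
(a SNP-only table cannot know how many monomorphic bases were callable).
θw = S/(a_n·L) with n = 2 × median non-missing diploids — one harmonic
constant per class keeps the estimator simple under site-varying
missingness. Heterozygosity is het calls per callable base per individual.
FST defaults to Hudson's estimator as the ratio of summed per-site
numerators and denominators (small-sample robust, no within-population
correction terms to destabilize at n = 5–17); Weir–Cockerham (haploid,
allele-count form) is available for comparison and recovers the same
simulated F. Pairs monomorphic across both populations are skipped and the
final ratio is clipped to [0, 1]. SFS routines use fully-called sites only;
unfolded spectra require a REF/ALT ancestral call.

## ROH and the inbreeding clock (`consgen.roh`)

The detector is a transparent greedy scan (the classical detectors do not
publish their internals): runs extend over consecutive non-missing calls; a
heterozygous call ends the run unless the running heterozygote count stays
within `het_per_mb` (default 1) per Mb of the current run. Segments are
SNP-delimited closed intervals, reported if ≥ 100 kb and ≥ 25 informative
sites. FROH divides summed retained lengths by the effective genome length
(default: first-to-last post-filter SNP span summed over chromosomes;
exposed because "effective length" is a reporting convention). The clock
g = 100/(2L) (L = mean segment length in Mb) estimates generations to the
haplotypes' common ancestor from the expected recombination erosion of IBD
tracts; years = round(g) × generation time (10 y default). L = 1.03 Mb
gives g ≈ 49, ≈ 490 years.

## Genetic load (`consgen.load`)

Deleterious: SIFT-like score < 0.05; tolerated: ≥ 0.05; synonymous: 4-fold
CDS regardless of score; everything unscored, unpolarized or non-coding is
excluded. The realized-load statistic is the homozygous-derived ratio: of
the deleterious sites where an individual carries ≥ 1 derived allele, the
fraction at which it is homozygous derived — invariant to adding tolerated
or synonymous sites. The masked/purged-load probe correlates per-individual
0-fold/4-fold heterozygosity ratio with intergenic heterozygosity (Pearson,
with Kruskal–Wallis and a BH-corrected pairwise compact-letter display
across populations). Population membership for the shared-load Venn is "≥ 1
homozygous individual" by default (a frequency-threshold rule is a config
switch; the unit of counting is genuinely a convention). Donor ranking:
candidates at the maximal adaptive-loci FST to the target are excluded
(outbreeding-depression guard), the rest ranked by the equal-weight mean of
within-criterion ranks (θπ↑, heterozygosity↑, FROH↓, hom-del ratio↓, shared
load↓, FST↓), ties broken by lower shared load. Equal weights are a policy,
not an inference; ranks make the composite invariant to monotone rescaling
of any criterion.

## Structure (`consgen.structure`)

The PCA scan standardizes dosages by sqrt(p(1−p)) after mean imputation,
regresses each SNP on the K leading PCs, and forms a Mahalanobis statistic
from the z-scores with a minimum-covariance-determinant estimate of their
null covariance — with the empirical covariance, genuinely outlying SNPs
inflate the spread and mask themselves. The statistic is rescaled by a
median genomic inflation factor against chi2(K) and thresholded by BH.

The admixture proxy factorizes G/2 ≈ Q·Fᵀ by alternating weighted ridge
least squares with Q rows projected onto the probability simplex and F
clipped to [0, 1]; an update is accepted only if the masked-training
objective does not increase, so the trace is monotone by construction.
Three restarts per K (the first spectral: k-means on leading PCs) avoid the
local optima the alternation can stall in; K* minimizes the held-out
squared error on 5% masked entries. The companion outlier scan computes,
per SNP, an FST-like differentiation statistic across the K fitted
ancestral frequency columns (weights = ancestry shares), chi2(K−1) after
median-GIF rescaling, BH at FDR 0.01. Adaptive loci are the intersection of
the two scans; everything else tested is neutral.

Neighbor joining follows the canonical Q-matrix agglomeration with the
standard two-point branch-length formulas and three-point closing; negative
lengths clamp to zero. The default sample distance is allele sharing
(1 − IBS). The implementation is cross-checked against an independent NJ
implementation and against exhaustive topology enumeration on additive
matrices in the tests.

## Genotype–environment association (`consgen.gea`)

Variables are pruned to pairwise |r| < 0.7 first. The univariate test
regresses population allele frequencies on each standardized variable with
weights proportional to sample size plus structure covariates — the leading
PCs of the population-frequency matrix. A PC with |r| ≥ 0.7 against the
tested variable is dropped from that variable's design: such a PC is a
proxy for the gradient itself and absorbs the association under test (on
planted fixtures this is the difference between recall ≈ 0 and ≈ 0.85).
The cost is anti-conservativeness when drift structure is genuinely
collinear with climate; with the generator's random population placement
the null hit rate stays far below the nominal q. BH q-values are computed
per variable; hits are q < 0.05 on any variable.

RDA centers sample dosages, fits them on the standardized environment by
least squares, takes constrained axes from the SVD of the fitted values,
and gates the loading scan on a global permutation test of the
constrained-variance ratio (rows of the environment permuted). On
significant axes, SNPs loading beyond ±3 SD of the axis mean are flagged
(two-tailed normal mass 0.0027) and attributed to their most correlated
variable. Candidates are the intersection of both methods' hit sets.

## Genomic offset (`consgen.offset`)

Responses are per-population frequencies of the globally minor allele for
SNPs with global MAF > 10%, optionally distance-thinned to 1 SNP/100 kb.
Each SNP gets a random-forest regression on the climate variables
(500 trees by default; mtry = ⌈p/3⌉, bootstrap resampling, out-of-bag R²).
Every split's impurity decrease is accrued to its predictor at its split
value; a forest's split mass is normalized to its R² so each SNP
contributes R²-weighted turnover, pooled over SNPs with positive R² into
200 equal-width bins per predictor and cumulatively summed into the
monotone turnover functions F_v (F_v(min) = 0). Overall importance is
F_v at the range top. GO at a cell is the Euclidean distance between
componentwise F-transformed future and current climate, values beyond the
training range clamped to its ends; per-GCM offsets combine by weights
(equal by default — the weighting scheme is a convention, exposed). GO is
zero under a zero shift, symmetric in the two climate states, and satisfies
the triangle inequality.

## Ensemble niche model (`consgen.enm`)

Presences are greedily distance-thinned (stable input order); predictors
pass pairwise-|r| < 0.7 then iterative VIF < 10 pruning; pseudo-absences
are sampled from non-presence cells (replicated sets). Five learners are
fitted per replicate per pseudo-absence set on 75/25 stratified splits:
natural-cubic-spline logistic (GAM-like), L1 logistic (lasso),
class-balanced random forest, gradient-boosted trees, and a
background-weighted quadratic logistic standing in for MaxEnt's penalized
exponential model. Holdout metrics: AUC, Somer's D = 2·AUC − 1, TSS (max
sensitivity + specificity − 1 over thresholds), continuous Boyce index
(Spearman of predicted-to-expected ratios over 10 overlapping suitability
windows). Only fits with Somer's D > 0 enter the ensemble, weighted by TSS
(normalized). The suitability threshold defaults to maximizing
sensitivity + specificity on the pooled holdout evaluations (sens = spec
and prevalence rules are switches — the printed threshold of any one study
is data-specific). NSC = current − future ensemble suitability per cell,
averaged over GCMs within a scenario (positive = deteriorating), and
suitable-area change is (current − future)/current × 100 over thresholded
cells.

## Pipeline (`consgen.pipeline`)

`run_pipeline(PipelineConfig)` runs simulate → filter →
popgen/roh/load/structure → gea → offset, plus the independent enm stage,
communicating only through written files and returned frames; the manifest
records the config hash (output path excluded), seed, completed stages and
a SHA-256 per output file. Reruns with the same config are bit-identical.
Stage failures abort downstream stages but keep partial outputs.

## Numerical conventions and degenerate inputs

Missing genotypes are −1 in int8 dosage matrices and excluded from every
count; frequencies use non-missing haplotypes only. Zero callable length,
zero retained ROH, all-missing sites, monomorphic SNPs in scans, empty hit
sets and single-class holdouts are all defined no-ops or flagged NaNs
rather than errors. All stochastic components take explicit seeds;
`n_trees`, permutation counts and replicate numbers are scaled down in the
test and acceptance configurations (40–100 trees, 49–199 permutations,
1–2 replicates) so the default suite and the acceptance script each finish
in a few minutes on one CPU; the statistical checks they support are
calibrated at those sizes.

## Known limitations

No haplotype phasing, no HMM-based ROH calling, no LD-aware null for the
outlier scans, no latent-factor mixed models for GEA, no dispersal or
land-use constraints in the niche models, and no demographic inference.
The univariate GEA's PC filtering trades false positives under
climate-confounded structure for power; the factorization's least-squares
objective is not the binomial likelihood, so ancestry fractions shrink
slightly toward the interior at small sample sizes.
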