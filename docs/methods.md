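# Methods

`cardiosnv` implements a single-cell whole-genome somatic SNV analysis for
post-mitotic tissues — burden estimation from MDA-amplified nuclei with a
tetraploid sensitivity correction, mutational-signature discovery and
artifact subtraction, mixed-effects aging regression, spectrum/strand and
functional analyses, and a ploidy-aware gene-knockout model — together with
a synthetic cohort generator that makes every stage testable end to end.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic validation does and does not establish.

## The synthetic cohort generator

The generator emulates, at the evidence-table level (downstream of
alignment), the data produced by single-cell WGS of MDA-amplified nuclei.

**Reference and germline.** An i.i.d. random genome (default 2 × 10 Mb,
GC 0.41) stands in for the autosomes. Phased germline heterozygous SNVs are
a Poisson process at 0.67 hets/kb (roughly the human heterozygosity scale),
each assigned uniformly to haplotype 1 or 2.

**Somatic truth.** Per cell, the somatic count is Poisson with mean
(μ + β·age) × G, where G = ploidy × haploid Mb is the cell's DNA content in
Mb, β is the cell-type accumulation rate and μ the burden at birth. Default
rates are the study conditions: 0.010 (cardiomyocyte), 0.003 (neuron),
0.009 (hepatocyte) and 0.004 (lymphocyte) sSNV Mb⁻¹ yr⁻¹; μ = 0.05 sSNV/Mb
(a few hundred genome-wide variants at birth, scaled to genome size). The
default donor panel is twelve donors aged 0.4–82.2 y (three infants, six
middle-aged, three aged), four cells each. Each variant's 96-class is drawn
from a signature mixture (default 0.7 SBS5-like + 0.3 SBS18-like) and a
genome position with the matching trinucleotide context is sampled
(forward-strand pyrimidine triplet or its reverse complement), with
collision-free resampling and a hard failure after 50 retries. Variants
land on one haplotype of one origin copy, uniformly.

**Amplification.** One *realization* is a diploid MDA amplification: per
site, a locus-dropout event (probability 0.10 by default) kills both
chromatids at once; surviving chromatids are lost independently with the
allelic-dropout probability (0.10). Live chromatids receive negative-
binomial read counts (dispersion r = 10) whose mean is the per-chromatid
depth times a log-normal per-100-kb amplification factor (σ = 0.3,
mean 1). Germline and (owned) somatic alleles occupy their chromatid
fully; MDA artifacts are sub-clonal on one chromatid with geometric(0.5)
alt support, injected at 2 artifact sites per Mb per realization with
contexts from the scF-like profile — C>T-dominated, as expected for
polymerase errors on single strands early in amplification.

**Linkage.** Each site links to its nearest phased het within a 500 bp
window (a proxy for the paired-end insert span; ties break to the lower
coordinate; germline hets link to their next-nearest neighbour). A read
from chromatid c covers the linked het with probability 1 − d/window, and
tallies into the (site allele × haplotype-of-c) linkage count.

**Tetraploid nuclei** are in-silico mixtures of two independent diploid
realizations sharing the germline, each at half the per-chromatid depth,
with read and linkage counts summed site-wise. Pre-endoreduplication
somatic variants (which would sit at 2/4 allele fraction) are not
generated: every somatic variant occupies one copy of one realization.

What the generator does *not* model: read-level base errors, indels and
SVs, CNVs, sex chromosomes, mappability structure, or reference bias.
Passing tests therefore demonstrate the internal consistency and
correctness of the estimators under this amplification model, not
robustness to every artifact of real data.

## QC

Locus dropout is operationalized as total depth < 5 at a germline het;
allelic dropout as a covered het where one allele has < 2 supporting
reads, with the denominator excluding locus-dropped sites (the inclusive
denominator is available by flag). Evenness: per-window read counts are
aggregated into variable-length bins holding equal expected reads under a
uniform baseline, ratios are corrected by the median of their GC decile
(with at least five bins per GC stratum so the correction cannot absorb
all variation on small genomes) and rescaled to mean 1. MAPD is the median
absolute difference of neighbouring bins' ratios, computed within
chromosomes on the linear (not log) scale; CoV is the sample s.d. over the
mean. On linear ratios MAPD saturates at extreme unevenness (the
normalization shrinks everything as a few huge bins dominate the mean), so
monotonicity in σ is only guaranteed below roughly σ ≈ 0.6.

## Linkage calling

A candidate (any non-germline site with ≥ 2 alt reads) passes *complete
linkage* when all alt-linked reads phase to exactly one haplotype h and no
ref-linked read phases to h. The per-cell threshold k on phasable alt
reads is the smallest k ≤ 10 with posterior P(true | support ≥ k) ≥ 0.9
under a two-component mixture — true somatic support Binomial(depth, AF)
with AF = 1/ploidy, artifact support Geometric(0.5) — with prior artifact
fraction 0.5 by default and fallback k = 2. "True-positive rate" is read
as precision (fraction of calls that are true), since that is what raising
the read threshold controls. Sensitivity in phasable regions is estimated
by pushing each phased germline het through the full calling rule as a
pseudo-somatic variant.

## Burden correction

Diploid: corrected count = raw calls / germline sensitivity; density =
corrected count / genome Mb, with genome Mb = (ploidy/2) × diploid genome
size (6,200 Mb default for real data; 2 × haploid reference length in
synthetic mode). Cells with sensitivity ≤ 0.01 are flagged QC-fail rather
than corrected, preventing unbounded correction factors.

Tetraploid dropout decomposes into the two (assumed equal) diploid
origins: L2 = √L4, and the per-copy allele-loss probability u solves
u² = L4 + (1 − L4)·A4 with A4 on a per-allele basis; a2 = (u − L2)/(1 − L2).
The QC estimator counts a site as allelic dropout when *either* allele is
under-supported, so the pipeline first converts the site-level rate via
a_allele = 1 − √(1 − a_site) (allele losses are approximately independent
given no locus dropout). The factorized sensitivity correction
s_tetra = s_germline × u × depth_factor is provided (depth_factor from
re-estimating sensitivity after binomial thinning of all read counts at
0.5, mirroring a read-downsampling analysis), **but the pipeline does not
use it**: a quarter-fraction variant is callable only when the duplicate
same-haplotype reference copy contributes no *linked* read, and that event
is strongly anti-correlated with the variant's own detectability through
the shared linkage geometry (in oracle measurements the joint pass
probability was ~0.04 against a marginal product of ~0.11). The pipeline
instead plants ~2,000 pseudo-variants into a model amplification of the
cell's germline and runs the actual caller; the pass fraction is the
sensitivity (Monte-Carlo s.e. ≈ √(s/n)). The plant parameters are the
amplification *model* parameters (configuration in synthetic mode, to be
calibrated by the user for real data) — feeding the measured depth<5 /
reads<2 rates back in would double-count read-level tails the simulation
reproduces itself. Estimating generative dropout parameters from the
operationalized rates is a known limitation.

Artifact subtraction: corrected density = density × (1 − w_scE − w_scF),
with weights from a non-negative least-squares refit of the cell's
96-class call profile onto the fixed panel. Refits on catalogues of fewer
than 50 calls are dominated by multinomial noise (leaking 10–25% weight
onto artifact signatures spuriously), so small cells take the weights of
the cohort-pooled call profile instead.

## Signatures

The 96 classes follow the COSMIC pyrimidine-strand convention (6
substitution types × 16 flanking contexts, alphabetical). De novo
discovery uses multiplicative-update NMF on the Frobenius objective
(monotone updates, tolerance 1e-6 relative, max 2,000 iterations, 50
restarts by default); the rank maximizing the cophenetic correlation of
the restart-consensus clustering is selected, ties toward the smaller
rank, and rank-1 is excluded from the candidate range since its consensus
is trivially perfect. Signatures are L1-normalized with exposures
rescaled; matching to references uses Hungarian assignment on cosine
distance. The shipped reference panel is **synthetic**: three
COSMIC-flavoured processes (SBS5-like clock, SBS18-like C>A, SBS44-like)
and two MDA artifact profiles (scE-like, scF-like), constructed with
pairwise cosines below 0.5; exact COSMIC matrices are deliberately not
bundled (version drift, licensing).

## Aging regression

Base model y_ij = β·age_j + μ + θ_j + ε_ij with a random donor intercept;
the cell-type model gives each type its own slope β + γ_k with a random
intercept per donor–cell-type pair. Coefficients come from the
maximum-likelihood fit. Inference is the place where the obvious choice
fails: with 10–12 donor clusters the ML likelihood-ratio test and ML Wald
intervals are markedly anticonservative (null rejection ~12% at the 5%
level; CI coverage ~82% in simulation). Standard errors are therefore
taken from the REML fit with a t reference distribution on between-donor
degrees of freedom (n_donors − 2) — simulation shows near-nominal
calibration — while the ML LRT p is still exposed as `p_lrt`.

For *corrected burden* outcomes a second issue appears: the density
raw/(s·G) carries a known Poisson measurement variance λ/(s·G)² that is
orders of magnitude larger in aged cells than infants at desk scale, and
this heteroscedasticity loads exactly on the highest-leverage points, so
even well-calibrated homoscedastic intervals undercover.
`fit_burden_age_model` handles this with a donor-level precision-weighted
meta-regression: measurement variances are taken as *model-implied*
(expected raw calls (μ + β·age)·G·s, iterated a few times) rather than
observed — weights built from observed counts correlate with the outcome
and shrink the slope — and the between-donor variance enters via a
DerSimonian–Laird moment estimator, with t inference on n_donors − 2 df.
This is the fit the pipeline reports for burden data; on simulated default
cohorts it is unbiased with near-nominal CI coverage. When the
donor variance component collapses to the boundary (singular Hessian), the
fit falls back to OLS with donor-clustered standard errors, the exact
τ = 0 limit. Covariates (e.g. MAPD, CoV, PMI) enter as fixed effects;
covariates correlated with age beyond |r| > 0.99 trigger a warning, and
cells with missing values are dropped with a warning.

## Spectra and strand bias

Age groups: infant ≤ 4 y, middle 30–66 y, aged ≥ 75 y (boundaries
inclusive so the study's 4.0 y and 75.0 y donors fall in their published
groups). The net-increase spectrum converts group proportions to absolute
counts via the group's mean corrected burden and subtracts infant from
aged; entries may be negative and the total equals the burden difference.
Strand assignment uses the pyrimidine representation against merged
per-strand gene intervals; sites under genes on both strands are excluded
as ambiguous. The strand-bias "Poisson test" is made concrete as the exact
two-sided binomial test of n_transcribed against Binomial(n, 1/2) — the
conditional form of comparing two Poisson rates. Being discrete, it is
conservative: its null rejection rate sits at or below nominal rather
than exactly at it.

## Functional impact

Genic annotation is codon-aware on one transcript per gene (severity
order stopgain > nonsynonymous > synonymous > UTR > intronic), with CDS
lengths validated as multiples of 3. Excess tests are two-sided Fisher
exact with the conditional-MLE odds ratio. Expression quartiles assign
ties to the lower quartile; quartile densities normalize by summed gene
length and mean per-cell detection power, with uncertainty from shuffling
quartile labels (1,000 rounds by default). Gene-set enrichment follows the
length-aware scheme: a monotone (isotonic) fit of the mutation indicator
on log gene length supplies per-gene weights, the per-set odds is the mean
in-set weight over the mean out-set weight, and the p-value is the upper
tail of the Wallenius noncentral hypergeometric (plain hypergeometric when
the odds are 1). Sets with more than 1,000 members or fewer than five
mutated members are excluded; the universe is restricted to genes with at
least one set annotation.

The cell-type-specific test ranks candidate sets (enrichment p < 0.01 in
either type) by p in each type and permutes gene labels of both tables
(preserving mutated counts) to build the null of the rank difference; the
empirical p uses the add-one estimator and is BH-adjusted. A structural
property worth knowing: under the uniform-rank null the probability of a
maximal rank difference is 1/C² for C candidates, so a single discovery
can only reach FDR < 0.05 when C ≳ 40 and the permutation count exceeds
~20·C. With equal gene lengths the permutation loop runs through a
vectorized hypergeometric path.

## KO model

n = corrected sSNV count × damaging fraction (default 36/10,407) × ploidy
factor (0.5 diploid, 0.125 tetraploid), and
Pr(KO | π, D, n) = π(1 − (1−D)^n) + (1 − π)(1 − e^{−nD}) with π = 0.17
(fraction of high-pLI, dosage-sensitive genes). D defaults to 1/n_genes (a
uniform per-gene hit probability) and is configurable, since only its
verbal definition is fixed; the small-nD linearization Pr ≈ nD holds to 1%
only when D itself is well below 1. Cell-level aggregation uses
1 − (1−q)^{G_eff} with G_eff = 1 by default (the formula read as already
cell-level; G_eff = n_genes exposed as the alternative). Diploid burdens,
when only tetraploid cells exist, are taken as 50% of the donor-matched
tetraploid burden. Donor curves carry mean ± s.e.m.; the exponential trend
is a log-linear least-squares fit on donor means (zero-probability donors
excluded), and the ploidy contrast is a two-sided paired Wilcoxon across
donors.

## Problem sizes and determinism

All simulation-backed validation runs on the 20 Mb default genome: the
slope-recovery check uses the full 12-donor × 4-cell tetraploid design for
20 seeds; the ploidy-equivalence check uses 16 aged (80 y) cells per arm
over three seeds so pooled call counts support the artifact refit, with
the 2× genome-burden ratio computed from counts pooled across seeds (a
single-seed mean-of-ratios at this genome size has ~20% Monte-Carlo CV
from ~2 raw calls per tetraploid cell). Every stochastic component draws
from `numpy` SeedSequence spawns of one explicit seed; identical seeds
reproduce byte-identical outputs, which the pipeline manifest verifies by
SHA-256.

## Known limitations

- Per-cell artifact weights are only meaningful above ~50 calls; below
  that the cohort-pooled weights are a shared approximation.
- The plant-based tetraploid sensitivity assumes the amplification model
  parameters are known or externally calibrated; inverting them from the
  operationalized dropout rates is not implemented.
- The mixed-model t inference runs slightly optimistic (~90% empirical
  coverage for nominal 95% at 12 donors).
- The generator's artifact model (geometric single-chromatid support) is a
  caricature of MDA chemistry sufficient for threshold calibration, not a
  sequence-context-faithful error model.
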