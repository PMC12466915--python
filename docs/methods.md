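# Methods

## The pseudo-survival Cox model

The central transformation treats each sequencing read of a phenotypic bin
as a pseudo-individual. For one variant, a bin with mean survival time
`t_k`, `m_k` reference reads and `n_k` alternative reads contributes `m_k`
REF deaths and `n_k` ALT deaths at time `t_k`; nothing is censored (the
cage design observes every fly to death). The proportional-hazards model

    h_i(t) = h_0(t) · exp(beta · GT_i [+ gamma · replicate_i])

is fitted by maximising the partial likelihood. With only K ≈ 7 distinct
event times and hundreds of tied deaths at each, the tie correction *is*
the likelihood: both the Efron (default) and Breslow corrections are
implemented, evaluated directly on the collapsed
`(time, ref_reads, alt_reads)` table. The collapsed table is the
sufficient statistic — the fit is identical (to 1e-10 in beta and its
standard error; verified by test) to the fit on fully expanded per-read
rows, so the collapse is an optimisation, not an approximation.

Numerics: damped Newton–Raphson from `beta = 0`, score max-norm tolerance
1e-9, at most 25 iterations, step-halving whenever a proposed step lowers
the log-likelihood. The halving guard uses a slack *relative* to |loglik|
(1e-10·(1+|ll|)); an absolute guard below float resolution stalls
convergence near the optimum on large tables. Complete separation (a
monotone likelihood, e.g. every ALT death preceding every REF death)
flattens out at extreme beta; any "converged" fit with |beta| > 15 is
reported as non-converged with NaN estimates and is excluded downstream.
Wald p-values on the GT coefficient are reported, matching what per-
coefficient survival software prints. The replicate enters the combined
model as a binary covariate (`time ~ GT + replicate`); a stratified-
replicate variant is available by flag. Replicate-specific fits use each
replicate's own bin mean times.

Candidate rule: per-replicate p < 0.05 in both replicates, consistent sign
of beta, and BH-adjusted combined p (q) < 0.01. BH adjustment runs over
all variants whose combined fit converged; the denominator is recorded in
the output (`n_tested`).

## Filters

Applied to the called-variant table before association, each evaluated
independently and reported per rule:

| rule | default | note |
|---|---|---|
| site quality | ≥ 20 | caller QUAL |
| pooled minor-allele count | > 5 autosome, > 2 X | strict inequality; minor = rarer of ref/alt in C1+C2, ties to alt |
| depth upper quantile | top 1% excluded | per chromosome class, guards against collapsed repeats |
| per-sample depth | ≥ 50 | each background sample; switch to include bins |
| indel proximity | ≤ 3 bp removed | inclusive window, indel positions supplied |
| replicate detection | both replicates | alt reads seen in ≥ 1 bin sample per replicate |

The per-sample depth rule reads "each sample" as the background samples
only by default — the minimal reading consistent with its purpose
(information content of the background frequency estimate); a
configuration switch extends it to the bin samples.

## Frequency-shift analysis

Alternative-allele frequency per bin is `alt/(ref+alt)` (undefined bins
skipped). All unordered bin pairs are labelled by level = difference of
bin indices; for K bins level L has K−L pairs (21 pairs, multiplicities
6..1, at K=7). Absolute differences from both replicates are pooled, and
candidates vs noncandidates are compared per level and jointly with a
two-sided Wilcoxon rank-sum test (normal approximation with tie
correction; exact enumeration when both groups together hold ≤ 12
distinct values, for testability against brute force).

## Enrichment

`ES = log2((a/(a+b))/(c/(c+d)))` with background = noncandidate variants
(flag for full-universe background). Fisher's exact test is two-sided for
categories (depletion is as meaningful as enrichment) and one-sided
(greater) for top-K gene-set overlap, which is framed as enrichment only.
Annotation priority when one variant carries several labels:
protein-altering (nonsense, missense) > synonymous > UTR (incl. uORF
start-codon labels) > intron > intergenic. A regulatory factor with more
than two interval tracks requires overlap of ≥ 2 distinct tracks for
membership — note this makes membership non-monotone in the number of
tracks exactly at the 2→3 crossover, which is covered by a regression
test. Genes are ranked by their best (minimum) variant q, ties broken by
variant count then gene id.

## Assays and sex-dependent classification

Mean survival is the arithmetic mean under complete mortality and the
Kaplan–Meier restricted mean when censoring is present (identical in the
all-event case). Group comparisons use the Mantel–Cox log-rank test. Sex
comparisons are made on `log2FC = log2(mean_kd/mean_ctl)` per sex, not on
absolute hours, because female baseline survival far exceeds male.
Classification order:

1. neither sex significant (log-rank p ≥ 0.05) → `no_effect`;
2. exactly one sex significant → sex-specific (direction from that sex's
   fold-change sign), regardless of the interaction term;
3. both significant, opposite signs → `antagonistic`;
4. both significant, same sign → sex-biased toward the sex with larger
   |log2FC| if the genotype×sex interaction (Cox Wald p on the product
   term, same engine as the association model) is significant, else
   consistent.

The mapping is total over the 36 discrete patterns (3 per-sex states ×
interaction × which sex has the larger fold change) and every pattern
lands in exactly one of the 12 categories. qPCR knockdown efficiency uses
the comparative-Ct method: technical replicates averaged within
biological replicate, ΔCt = Ct_target − Ct_reference, relative expression
2^−(ΔCt_kd − mean ΔCt_ctl); sex bias is tested per phenotype category by
paired t over gene means and per gene by two-sample t across biological
replicates with BH adjustment.

## Simulator

The generator emulates the cage design end to end: haploid male genotypes
Bernoulli(freq) per locus (a diploid switch exists), survival times from
an exponential baseline (mean 80 h, within the observed survival range;
Gompertz optional) scaled by exp(Σ beta·g), equal-count binning into 7
bins (remainder to the earliest bins, mimicking death waves; fixed
12-hour collection windows optional), and Pool-seq as Poisson depth
(default mean 200) with binomial allele sampling at the bin's true pool
frequency, miscalled symmetrically at rate 1e-3. Two independent cages of
2000 individuals form the two replicates. Assay simulation draws
exponential survival with sex-specific baselines (90 h female, 60 h male)
scaled by exp(effect_sex) under knockdown. Where the design leaves a
constant free (per-locus allele frequencies), U(0.1, 0.9) is used:
polymorphic and unexceptional for segregating natural variation.

What it does **not** emulate: linkage disequilibrium (loci are unlinked),
strain block structure (individuals are independent; real cages pool 10
flies per isofemale strain, so strain frailty would add extra-binomial
noise), read-level error profiles beyond a symmetric rate, and interval
censoring of collection times. Passing tests therefore demonstrate the
statistics under an idealised cage, not robustness to LD or kinship.

## Measured calibration behaviour

The pool frequency observed in a bin carries two noise layers: sampling
of individuals into bins (variance ≈ p(1−p)/n_bin) and read sampling
(≈ p(1−p)/depth). The read-level Cox model accounts only for the second,
so its test is well calibrated exactly when depth ≪ individuals-per-bin
and grows anticonservative as depth approaches and exceeds the bin size.
Measured on 2000 null loci (2000 flies, 7 bins): per-replicate
p < 0.05 rate ≈ 0.047 at depth 30 (≪ 285 flies/bin) but ≈ 0.11–0.14 at
depth ≈ 285 — close to the ≈ 2× variance inflation predicted at
depth = bin size. This is a property of read-level pseudo-replication in
the design itself, not of the optimiser; the package reports it rather
than hiding it. The three-part candidate rule remains conservative under
the null (candidate rate 0 ≤ 0.01 in the same runs) because the combined
FDR gate dominates. Users mapping real data at depth ≳ individuals
should treat per-replicate p-values as anticonservative screening
statistics and rely on the replicated three-part rule.

## Problem sizes

Simulation-based measurements use 2000 null loci for calibration, 50
seeds per effect size for sign-recovery/power, 50 runs for antagonism
classification, and exhaustive enumeration of all 2×2 tables with total
≤ 30 (44,515 tables) for the Fisher oracle — sizes at which every rate
above is stable to the first decimal while a full run stays within a few
minutes on one CPU.

## I/O conventions

Long-form TSV is the canonical counts format (chrom, pos, ref, alt,
sample, ref_reads, alt_reads); VCF 4.x with per-sample AD is mapped onto
it. Only biallelic SNVs are analysed; multi-allelic or indel records are
rejected at read time with a count of rejections. All internal positions
are 1-based; BED input (0-based half-open) is converted on read, so
`[s, e)` covers 1-based positions s+1..e. Result tables round-trip
losslessly through `write_results`/`read_results` (floats at 12
significant digits).
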