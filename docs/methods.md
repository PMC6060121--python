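# Methods

## The problem

Genomic imprinting silences (or strongly suppresses) one parental copy
of a gene, so an imprinted gene expresses almost exclusively one
allele.  In bulk RNA-seq of a cohort, imprinting leaves a fingerprint:
at heterozygous SNPs inside the gene, nearly all reads carry one
allele, in every individual.  `aseimprint` quantifies this allelic bias
per individual and gene, screens a transcriptome-wide ranking for
imprinted genes, and models how the bias depends on biological
(diagnosis, age, genetic ancestry, sex) and technical (RIN, sequencing
batch, brain bank) covariates.

## The read count ratio

For individual *i* and gene *g*, let the sum run over the SNPs *s* at
which *i* is usably heterozygous in *g*, with per-SNP total read count
T_s and higher-allele count H_s = max(ref_s, alt_s):

    S_ig = H_ig / T_ig = (Σ_s H_s) / (Σ_s T_s).

S ranges from 0.5 (balanced) to 1 (monoallelic).  The statistic is
parent-agnostic: it folds the unknown phase by taking the larger
count.  Folding has two consequences the package accounts for
explicitly:

- **Positive bias at balance.**  Even for a perfectly biallelic gene,
  E[S] > 0.5, with excess of order T^(-1/2).  Tests assert this against
  exact enumeration of Binom(T, 0.5).
- **Reliability grows with bias.**  If B ~ Binom(T, p) is the count of
  the truly biased allele, Pr(H = B | p) = Pr(2B ≥ T) is monotone in p
  and → 1 as p → 1 (`quantify.prob_higher_is_biased`).  This justifies
  restricting inference to high-S genes.

A per-SNP tie (ref = alt) has no higher allele; max is still well
defined and contributes H_s = T_s/2, so every usable SNP enters the
sum.  Cells with no usable SNP are missing data and are never imputed.

## Filters and genotype calibration

Defaults follow the canonical analysis and are all configuration keys:

| filter | default | boundary semantics |
|---|---|---|
| SNP call quality (Phred) | > 20 | strict |
| dbSNP membership | required | — |
| total alleles | ≤ 2 | inclusive |
| reads in at least one sample | ≥ 10 | inclusive |
| heterozygosity confidence L_het | ≥ 0.95 | inclusive |
| RNA coverage per usable SNP | ≥ 7 | inclusive |
| cell total read count t_rc | ≥ 15 | T = 15 kept |
| individuals per gene t_ind | ≥ 25 | 25 kept |

Filters are applied sequentially and removal tallies are logged in
application order.  Array genotype calls carry L_het = 1 by definition;
imputed calls carry their imputation confidence.  DNA/RNA discordance
(a het DNA call with monoallelic RNA) is reported per source; a source
with no usable calls yields an undefined (not zero) rate.
"Monoallelic" means the minor allele has ≤ 0 reads by default; the
threshold is configurable.

The individual-exclusion rule for imputation errors is genuinely
ambiguous in scope, so three policies are implemented and named rather
than guessing an intent: `contradiction` (default — drop an
(individual, gene) block when its imputed, well-covered het SNPs are
purely-reference at one SNP and purely-alternative at another),
`global` (same trigger drops the individual everywhere), and `off`.

## Transforms

Quasi-log, with pseudo-count c = 1 (natural log):

    Q_ig = −log(1 − S_ig · T_ig / (T_ig + c)) ∈ (0, log(T + c)].

Rank transform, within gene across individuals, ties sharing the
maximal rank:  R_ig = #{j : S_jg ≤ S_ig} / #j × 100 ∈ (0, 100].
Q is computed after filtering, on the filtered T.

## Calling imprinted genes

The gene score is the upper tail of the across-individuals ECDF of S:
score = 1 − F_g(0.9), i.e. the fraction of individuals with S > 0.9
(strict).  Genes are ranked by score; ties break by the looser score
1 − F_g(0.7), then by gene identifier, making the ranking a
deterministic permutation.

Two screens separate imprinting from look-alikes:

1. **Reference/nonreference allele test.**  Imprinting picks the
   silenced allele by parental origin, independent of ref/alt identity,
   so at each SNP the count of individuals whose *reference* allele has
   the higher count is Binom(n, 0.5).  Reference mapping bias or a
   cis-eQTL pushes all individuals the same way.  Per SNP we run an
   exact two-sided binomial test (two-sided because a cis-eQTL can
   favour either allele); individuals with tied counts are excluded,
   and SNPs with fewer than 10 informative individuals (configurable)
   do not count.  Gene-level decision: "X" when the number of rejected
   SNPs exceeds the 95% quantile of Binom(#informative SNPs, α) — this
   compound rule holds the gene-level false-flag rate near 5% — and
   "0" when no SNP is informative.
2. **Nearly-unbiased-expression test.**  A cell is certified nearly
   unbiased when S ≤ 0.6 and UCL ≤ 0.7, where
   UCL = S + z_0.975 √(S(1−S)/T) is the normal-approximation 95% upper
   confidence limit of the expected ratio (z_0.975 = 1.959963984540054,
   hard-coded at double precision).

Prior status is `known_imprinted` (on a user-supplied list),
`nearby_candidate` (minimal interval distance to a known imprinted gene
on the same chromosome < 1 Mb; overlap counts as 0), else
`distant_candidate`.  Coordinates are 1-based closed intervals.  The
final call: rank ≤ 50 **and** prior status known/nearby, plus an
explicit manual-include list for established imprinted genes ranking
just below the cutoff.

## Regression models

The response is a transform of S (quasi-log Q by default) on the
(individual, gene) cells of the called imprinted genes.  Two model
families share one formula grammar:

- **Fixed (per-gene)**: OLS (`unlm`) or WLS (`wnlm`) per gene.  The
  `wnlm` weights are proportional to T_ig: var(S) ∝ 1/T under the
  binomial model, so T is the natural precision proxy.  (The weighting
  variable is a package choice; nothing in the underlying analysis
  pins it down.)
- **Mixed (all genes jointly)**: y = Xβ + Zb + ε with ε ~ N(0, σ²I),
  b ~ N(0, Ω).  Each random term `(1 + slopes | factor)` is a batch;
  within a batch all levels share one unstructured covariance block
  (intercept and slopes correlated); distinct batches are independent.
  A batch with L levels and m slopes contributes L·(1+m) columns to Z.

Estimation is **maximum likelihood, never REML**, so AIC and
likelihood-ratio comparisons stay valid when models differ in fixed
*or* random terms.  The implementation profiles β and σ² out of the
deviance and minimises

    −2ℓ(θ) = log|ΛᵀZᵀZΛ + I| + n(1 + log(2π r²(θ)/n))

over the per-batch Cholesky parameters θ of the relative covariance
factor Λ, where r² is the minimised penalised residual sum of squares.
The optimiser is L-BFGS-B with diagonal parameters bounded at 0, run
from two fixed starting scales (1.0 and 0.1 on the Cholesky diagonal);
the objective is deterministic, so fits are exactly reproducible.
Convergence tolerance is 1e-12 on the relative deviance change.  A
diagonal parameter ending at the zero boundary flags the fit
`singular` (not an error); all of that batch's predictions are then
exactly zero.  Correctness is checked two independent ways: brute-force
multivariate-normal density evaluation of the marginal likelihood, and
an R/lme4 ML fit of the same data (agreement to ~1e-4 in log-likelihood
on the test instance).

Term tests fit the model with and without one term (everything else
kept) and report ΔAIC = AIC_with − AIC_without and the χ² statistic
2·Δlogℓ on df = number of added parameters.  For variance components
the null lies on the boundary of the parameter space, so the naive χ²
reference is conservative; this is documented and *tested* (null
rejection rate below nominal), not corrected.  Model selection is a
greedy forward AIC search over an ordered candidate list with a full
audit trail; it can express the structure of a rich model such as

    Q ~ RIN + (1|RNA_batch) + (1|Institution) + (1|Institution:Individual)
      + (1|Gene:Institution) + (1|Gender:Gene)
      + (Age + RIN + Ancestry.1 + Ancestry.3 | Gene)

Gene-specific coefficients in the mixed model are *predicted*
(conditional means, b̂ = Λû at the optimum) without confidence
intervals; the per-gene fixed models provide estimates with CIs at
lower power.  Residual diagnostics report the normal-quantile
correlation of residuals (Blom positions; flag below 0.99) and the
slope of |standardised residual| against standardised fitted values
(flag above 0.1 in absolute value).

## The synthetic cohort

The generator's defaults are the study conditions everything else is
tested under: 579 individuals (267 control / 258 SCZ / 54 affective
disorder), 2000 genes of which 30 are imprinted and 10 are
reference-mapping-bias contaminants, 1 + Poisson(2) SNPs per gene,
negative-binomial coverage (mean 20, size 5).

True allelic bias follows a logistic link confined to the folded
statistic's support:

    p_ig = 0.5 + 0.5·expit(μ_g + z(Age_i)·α_g + Anc1_i·γ1_g
                           + Anc3_i·γ3_g + offsets),

with age standardised inside the link ((Age−55)/20; ages themselves
stay in years).  Imprinted genes draw a baseline p in [0.90, 0.99]
(μ_g = logit((p−½)/½)); biallelic genes use μ_g = −6 (p ≈ 0.5012);
contaminants draw p in [0.85, 0.95] with the biased allele *always* the
reference allele, whereas all other genes assign it uniformly per
(individual, SNP).  No magnitudes for the age/ancestry/sex effects
exist in the underlying analysis, so the defaults (SD 0.3 for age and
ancestry slopes on the link scale, 0.1 for sex, 0 for diagnosis) were
chosen once for detectability at n = 579 and are synthetic, not
empirical.  Counts are beta-binomial with overdispersion ρ
(default ρ = 0, the pure binomial assumption; ρ > 0 exists to make
robustness testable).

Genotypes are Hardy–Weinberg draws at MAF ~ U(0.1, 0.5); half the SNPs
are array-typed (L_het = 1), the rest imputed with L_het ~ Beta(30,
1.5) and an error curve err(L) = 0.6(1−L) (3% at the 0.95 cutoff): an
erroneous het call sits on a truly homozygous genotype, so its RNA is
monoallelic.  Imprinted genes are laid out in clusters (100 kb
spacing) with one biallelic neighbour inside 1 Mb, so the proximity
rule is exercised in both directions, and a few imprinted genes are
withheld from the known list to exercise the `nearby_candidate` path.

What the generator does **not** emulate: read-level artefacts
(alignment, PCR duplicates), phased haplotype consistency of the biased
allele across a gene's SNPs within an individual, linkage between
SNPs, gene-expression covariance, or the actual imputation algorithm
(only its error process).  Passing tests therefore demonstrate the
statistical machinery under the model's own assumptions, not robustness
to every real-data pathology.

## Problem sizes used in tests

The test suite and `scripts/acceptance.py` run the cohort-scale
detection check at the full 579 × 2000 default; mixed-model
correctness uses 30 genes × 200 individuals (variance recovery, 50 and
20 replicates respectively), 10 genes × 60 individuals × 100–200
replicates (null calibration of the diagnosis term), 20 genes × 100
individuals × 50 replicates (power of the gene-specific age slope) and
20 genes × 500 individuals (slope prediction).  These sizes are the
package's chosen compromise between Monte-Carlo error and turnaround.

## Known limitations

- One gene per SNP: overlapping-gene SNPs must be resolved upstream
  (duplicated rows are rejected with an error).
- The compound decision rule of the reference/nonreference test and
  the 10-informative-individuals floor are package choices; the
  gene-level flag is calibrated near 5% under the null by
  construction, not inferred from any external source.
- Naive χ² df counting for variance-component tests (boundary
  conservatism documented above).
- The mixed-model optimiser is dense in the random-effect dimension q;
  it is comfortable up to a few thousand random coefficients, which
  covers the intended designs (including individual-level intercepts),
  but is not built for q ≫ 10⁴.
- `unlm`/`wnlm` on transformed responses are the only model classes
  registered; the class registry is extensible but other link/error
  combinations are out of scope.
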