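# Methods

This note documents the models, algorithms and numerical conventions behind
epibench, the choices made where the design was genuinely open, and what the
synthetic data do and do not establish about real GWAS.

## Synthetic template panels

Real benchmarking pipelines resample a reference genotype panel (e.g. a
continental subset of a sequencing project restricted to a genotyping chip's
markers). epibench generates the panel itself so the whole study is
reproducible from a seed.

Each chromosome is partitioned into contiguous blocks with lengths drawn
uniformly from `block_len_range` (default 5–10 markers, roughly one LD block
at 500K-chip density). Within a block, every haplotype descends from a pool
of `n_founders = 4` founder haplotypes that are all copies or complements of
one random block pattern, so pre-noise inter-locus correlation is |r| = 1.
Founder selection weights give the block's carrier type a frequency q drawn
uniformly from `maf_range`. Per-locus replacement noise (with probability ε
the allele is redrawn from its marginal law) attenuates pairwise r² by
(1−ε)⁴ without moving allele frequencies; ε = 1 − (within_block_r2)^¼
therefore targets the requested typical within-block r². Empirical MAFs are
enforced by regenerating a block (up to 1000 attempts) until every locus
lands inside `maf_range`; a range containing no attainable frequency
k/(2·n_templates) is rejected up front. Genotypes are the sum of two
independently drawn haplotypes (random union); codes count the panel-minor
allele, an orientation frozen at creation and inherited downstream.

What this emulates: multi-level LD within blocks, independence across
blocks, a realistic MAF spectrum. What it does not: recombination-map decay
of LD with distance, inter-block leakage, population structure, genotyping
error, missingness. Tests passing on these panels show the pipeline's
statistics and bookkeeping are correct; they do not certify behaviour under
structure or differential missingness.

QC mirrors standard template filters: MAF ≥ 0.05 and a 1-df χ² goodness-of-
fit test of Hardy–Weinberg equilibrium at p ≥ 10⁻³ (the χ² test, not the
exact test, is the convention at hundreds of templates; monomorphic loci
return p = 1 and are caught by the MAF filter).

## Population resampling

For each simulated individual and chromosome: a start locus d is drawn
uniformly among positions whose (2l+1)-window fits in the chromosome; that
window is copied from a uniformly drawn template; the remainder is grown one
locus at a time, drawing the new genotype uniformly among templates whose
genotypes match the already-simulated trailing window of 2l loci (rightward,
then the mirror-image leftward pass). Matching operates on unphased 0/1/2
genotype vectors. Default l = 5 (window 11 markers), exposed as a parameter.

When no template matches, the matcher shrinks the window one locus at a time
from the end farthest from the target locus until a template matches, and
falls back to the locus's marginal template distribution only for an empty
window. Every shrink is counted in `fallback_count`; on panels generated by
this package fallbacks are rare (often zero), and a large count signals that
the panel is too small for the window length. Support preservation is
structural: a simulated genotype value always exists at that locus in some
template.

## Disease scenarios and penetrance

The scenario grid crosses MAF pairs {(0.15, 0.15), (0.3, 0.3)}, LD
r² ∈ {0, 0.2, 0.5}, dominant main effects {(1,1), (1.5,1.5), (1,1.5)} and
per-model interaction strengths (dominant-dominant, multiplicative,
alternative: ρ ∈ {2,3,5}; recessive-recessive: {2,5,10}; the null model has
none) at prevalence K = 0.15 — 234 scenarios in all.

Two-locus genotype frequencies take the positive-D haplotype solution
D = √(r² f_a(1−f_a) f_b(1−f_b)) (the sign is not identified by r²; positive
association of minor alleles is the conventional choice) followed by random
union of haplotypes. Infeasible r² values are rejected with the feasible
maximum named.

The penetrance solve is closed-form: with the relative-risk surface fixed by
the product formula R_ij = r_{a,i} r_{b,j} ρ_ij, prevalence is linear in the
baseline, p₀₀ = K/E[R]. A scenario whose implied penetrance exceeds 1 —
which happens for strong interactions at low MAF, e.g. the dominant-dominant
model above ρ ≈ 12.6 at f = 0.15 — raises an infeasibility error rather than
clipping; 156 of the 234 grid scenarios are feasible at K = 0.15. The
"marginal risk ratio" of a scenario is interpreted as the conditional-on-
genotype ratio of the product formula, not the population-averaged ratio
after LD mixing; the achieved marginal ratio can be computed from the
penetrance table as a diagnostic.

`penetrance_to_logit` / `logit_to_penetrance` give the exact (lossless)
logit-scale decomposition into intercept, two length-2 main-effect vectors
and a 2×2 interaction block; β_ab = 0 iff the table is logit-additive, the
working definition of "no epistasis".

Causal-pair selection minimizes
(f̂_a−f_a)² + (f̂_b−f_b)² + w(r̂²−r²)², w = 1, over cross-chromosome pairs
when the LD target is 0 and within-chromosome pairs closer than 1 Mb
otherwise — the restricted candidate set returns the same optimum as a fully
exhaustive search on panels of this construction at a fraction of the cost.

## Cohort sampling and waffect

Inclusion weights follow p_gwas = n₁p_k/(mK) + n₀(1−p_k)/(m−mK), capped at 1
(with a warning if more than 0.1% of individuals are capped). Selection
without replacement uses numpy's sequential weighted draws. Phenotypes on
the selected subset are assigned by waffect: the law of independent
Bernoulli(p_i) conditioned on exactly n₁ successes, sampled exactly via a
backward DP B[i][j] = P(suffix i.. has j successes) in log space
(log-sum-exp; stable for thousands of individuals and small penetrances)
followed by forward conditional draws. `waffect_sample` amortizes the DP
across replicate draws with a shared probability vector. The cohort case
count is exactly n₁ in every replicate by construction.

The direct two-SNP simulator inverts the model by Bayes' rule,
P(G|D) = P(D|G)P(G)/K and P(G|D̄) = (1−P(D|G))P(G)/(1−K), and draws case and
control 3×3 tables as multinomials — the appropriate generator for power
work where only the causal pair matters.

## The five statistics

All five operate on the 2×3×3 table and share a uniform degeneracy
convention: a table the statistic cannot absorb (empty required cell,
monomorphic SNP in a group, singular covariance) scores 0 with p = 1 and a
`degenerate` flag, so no score ever diverges on sparse tables. The
probability that a 1000-sample study lacks the double-recessive cell for two
loci of uniform MAF in [0.05, 0.5] is ∫(1−f⁴)¹⁰⁰⁰df/0.45 ≈ 0.25, so this
convention is exercised constantly at scale.

* **fastepi.** Each individual contributes its four allele pairings to a 2×2
  joint allele table per group (total 4n); the statistic is
  Z² = (ln OR_case − ln OR_ctrl)²/Σ1/T over the eight cells, χ²₁. The
  four-pairing count (rather than a half-weighted 2n table) is what
  calibrates the statistic under the no-LD null — the half-weighted variant
  is conservative by an order of magnitude (measured type-1 error 0.007 vs
  0.052 at α = 0.05).
* **SHEsisEpi.** Pearson correlation of the 0/1/2 codes per group from the
  3×3 table; Fisher z difference standardized by √(1/(n₁−3)+1/(n₀−3)),
  squared, χ²₁.
* **GBOOST.** Exact likelihood-ratio test of the saturated binomial model
  against the main-effects logistic model, computed as the deviance of the
  log-linear model with margins [DA][DB][AB] fitted by IPF (convergence:
  max fitted-count change < 10⁻⁹, cap 5000 sweeps), χ²₄. Verified to agree
  with an IRLS-fitted GLM to < 10⁻⁶ on random tables. No screening
  approximation is used for power work; the score-30 screen is available for
  genome-scale scans only.
* **IndOR.** Φ = case-minus-control differences of the four adjacent-cell
  local log odds ratios; V_Φ by the delta method (inverse counts with
  shared-cell covariances); Wald statistic ΦᵀV_Φ⁻¹Φ, χ²₄; zero score when
  any required cell is empty or cond(V_Φ) > 10¹².
* **DSS.** Piecewise-linear ROC through the 9 genotype cells ranked by
  case:control density ratio, compared at each vertex against the better
  single-SNP ROC (linear interpolation at the vertex FPR); the statistic is
  the largest one-sided z² for the TPR gain (both proportions on n₁), with a
  Bonferroni factor for the number of vertices; reported as −log₁₀ p. The
  original software's prefilter is deliberately not applied — all pairs are
  scored. The exact published formulations of SHEsisEpi, IndOR and DSS live
  in their original papers; the operationalizations above are this package's
  frozen definitions of the same ideas (LD contrast on the 3×3 table;
  odds-ratio-independence contrast with zero-score singular handling;
  ROC-gain score) and are documented here precisely so results are
  interpretable against them.

p-values come from the asymptotic χ² law via `chi2_log_sf`, computed in
log10 space so chip-wide thresholds like 0.05/1.25×10¹⁰ are representable
without underflow.

## Evaluation layer

SNP-level: the true-positive indicator is the causal pair beating the
threshold; the false-positive rate is the count of sub-threshold non-causal
pairs over the total number of pairs. Block-level: SNP pairs map to LD-block
pairs; a block pair is detected when any member SNP pair passes; the causal
block pair must involve two distinct blocks (same-block causal pairs are an
error; intra-block detections are outside the block-pair universe). With
singleton blocks the two levels coincide exactly, which is asserted as an
invariant. Per-replicate AUC is the normalized rank of the single causal
pair among all pairs (ties averaged): 1 = top-ranked, 0.5 = random.

Block construction is a deliberately simple greedy builder — a block absorbs
the next locus while r² with the block's first locus stays above `r2_min`
and the span stays within 500 kb — because confidence-interval haplotype-
block algorithms are external tooling, not part of this package's
contribution; block maps produced elsewhere can be supplied instead.
Bonferroni thresholds are computed in log space; Benjamini–Hochberg step-up
selection is provided for data-analysis-style FDR control.

## Power and ρ₀.₈

Power is the fraction of replicates (default 1000) in which a method's
p-value on a simulated two-SNP table beats the threshold (default
0.05/1.25×10¹⁰, the printed chip-wide Bonferroni constant for a 5×10⁵-SNP
design; the exact pair count 1.2499975×10¹¹ is also exposed). Replicate r
always derives its seed from (seed, r), so power evaluations at different ρ
share common random numbers and the power curve is near-monotone despite
Monte-Carlo noise.

ρ₀.₈ is found by bracketing the first upward crossing of 0.8 on a coarse ρ
grid (step 0.5) and localizing it with Brent's method (xtol = 0.05). Two
boundary behaviours matter: (i) the upper bracket is clipped to the largest
feasible ρ (penetrance ≤ 1), found by bisection; (ii) the power curve is not
monotone over the whole range — at extreme ρ the control table's carrier
cells empty out and the degenerate-score convention collapses every
statistic — so a naive two-point bracket would misclassify strong-effect
designs as undetectable. A family whose power never reaches the target in
the feasible range is reported as "> cap" (cap 20).

Problem sizes throughout (panel of ~80–200 templates and a few hundred loci,
populations of 2 000–20 000, 1000-replicate power estimates, 5000-replicate
null calibration) are chosen so a full analysis runs in seconds to a minute
on one CPU while keeping Monte-Carlo standard errors at the third decimal;
all of them scale up through ordinary function arguments.

## Known limitations

* The resampler treats all chromosomes as autosomal and ignores sex.
* No missing genotypes, covariates or population structure anywhere.
* The greedy block builder is not the Gabriel confidence-interval algorithm;
  block-level rates on real data should use externally computed block maps.
* Published two-SNP power tables for these methods depend on implementation
  conventions of the original software stack (allele-counting variants,
  penetrance-solve details) that their descriptions underdetermine;
  cross-implementation ρ₀.₈ values should be expected to agree in pattern
  and scale (and do, at larger cohort sizes) rather than digit-for-digit.
* Genome-scale campaigns (10⁵ SNPs × hundreds of replicates) are out of desk
  scope; the pair scanner guards at 20 000 loci unless forced.
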