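# Methods

## The statistical problem

Two case-control GWAS of different traits share subjects. At a null SNP,
each study's association z-score is (approximately) normal, but the two
z-scores are correlated through the shared subjects, and each study's
marginal variance exceeds 1 under polygenicity or residual confounding.
Looking up trait 1's index SNPs in trait 2's results therefore produces an
excess of nominal "replications" even when no locus is truly shared.
`crosstrait` removes this artifact by modelling the null pair and testing
against its conditional distribution.

## The bivariate null and the conditional transform

At a null SNP, (z₁, z₂) ~ N(0, [[σ₁², c], [c, σ₂²]]).

* **σ₁², σ₂²** are estimated as the mean of z² across a well-imputed,
  genome-wide SNP set (`estimate_inflation`). This is the mean χ² statistic;
  the caller chooses the SNP set (a HapMap3-like set is the intended use).
  An estimate from fewer than 100 SNPs triggers a warning.
* **c** (`theoretical_overlap_cov`) follows from the sample counts of two
  overlapping case-control studies under zero genetic correlation:

      c = [ nₛᶜ √((N₁ᵗN₂ᵗ)/(N₁ᶜN₂ᶜ)) + nₛᵗ √((N₁ᶜN₂ᶜ)/(N₁ᵗN₂ᵗ)) ] / √(N₁N₂).

  The formula is symmetric in the two studies, equals 0 without overlap and
  1 for two identical fully-overlapping studies. It is undefined (raises)
  when any per-study case or control count is zero. Subjects who switch
  case/control status between studies are not modelled.
* Alternatively **c** can be estimated from data (`empirical_overlap_cov`):
  the mean z₁z₂ product over null SNPs, or — robust to true genetic
  correlation — the intercept of the OLS regression of z₁z₂ products on LD
  scores (the cross-trait LD-score-regression intercept). Only the
  intercept estimator is implemented; slope-based heritability and
  genetic-correlation estimation are out of scope.

The corrected statistic is the standardized conditional residual

    z_corr = (z₂ − μ)/τ,  μ = (c/σ₁²) z₁,  τ² = σ₂² − c²/σ₁²,

with two-sided p = 2Φ(−|z_corr|). Standardizing by the full conditional
variance τ² (which contains study 2's polygenic inflation σ₂²) is a
deliberate, conservative choice: at truly associated SNPs part of σ₂² is
signal, so the corrected test under-rejects rather than over-rejects.
`variance_mode="unit"` substitutes 1 for σ₂² as a sensitivity analysis.
The conditioning direction is a parameter — the same transform serves the
reverse lookup (trait 2's hits in study 1) by swapping the model.

## Imputation and meta-analysis

Untyped SNPs are imputed per LD block as the conditional mean of the
block's multivariate normal: z_t = wᵀ(Σ + λI)⁻¹ z_typed, with predicted
accuracy r²pred = wᵀ(Σ + λI)⁻¹w clipped into [0, 1] (clipping only guards
floating-point undershoot). The ridge λ defaults to 0.1, the standard
regularizer for summary-statistic imputation against finite reference
panels; at λ = 0 an ill-conditioned typed-submatrix (condition number
> 1e12) raises rather than returning noise. Imputation never crosses block
boundaries. No r²pred filter is applied by default (`min_r2pred = 0`);
typed SNPs always survive filtering.

Meta-analysis uses the sample-size-weighted scheme: wᵢ = √Nᵢ with
Nᵢ = cases + controls by default; an effective-sample-size option
4/(1/Nᵢᶜ + 1/Nᵢᵗ) is available for very unbalanced designs. SNPs present
in a single study pass through with that study's z; `require_all`
restricts to the intersection. Inverse-variance meta-analysis and
heterogeneity statistics are intentionally absent.

## Shared-locus enrichment

Index SNPs are filtered before lookup: X-chromosomal variants (chrom X or
23) and indels (any allele longer than one base, or symbolic I/D/<...>
alleles) are excluded because the Gaussian imputation operates on an
autosomal SNV reference; survivors are intersected with the target study.
Every exclusion is tallied by class. Nominal hits are counted with strict
inequality p < α (α = 0.05). The enrichment test is the exact binomial
upper tail P(X ≥ k | n, p₀ = α), summed in log space (gammaln +
logsumexp) so that p-values near 1e-8 and far smaller are exact; the
implementation is cross-checked in the tests against independent
exact-fraction summation and against `scipy.stats.binom.sf`. Per-SNP
multiplicity uses Bonferroni, m = the total number of lookups performed
across both directions of the cross-trait query; corrected values above
0.9999 are displayed as ">0.9999". Direction concordance counts
sign(z₁) = sign(z₂) pairs after allele harmonization; a zero z counts as
discordant and is flagged.

Allele harmonization aligns study 2's record to study 1's effect allele:
swapped alleles negate z; strand complements are resolved; A/T and C/G
pairs are strand-ambiguous, retained but flagged (a `--drop-ambiguous`
switch removes them). A record whose alleles neither match, swap, nor
complement raises — never silently dropped. z-scores derived from p-values
require an explicit direction column; unsigned p-only records are
rejected.

## LD intervals and gene-set enrichment

Intervals around index SNPs span the leftmost-to-rightmost panel SNP with
r² ≥ threshold to the index SNP (default 0.5, configurable — the
analysis's own interval threshold is not published), plus optional
padding; overlapping intervals merge, pooling index ids, so the tested
intervals are LD-independent. An index SNP absent from the panel
degenerates to its position ± pad with a warning. A candidate hit in
r² > 0.8 LD with an index SNP of the other trait is excluded as an LD
proxy of the same signal (`exclude_ld_proxies`).

Gene assignment uses closed-interval intersection with genes extended by a
flank (default 50 kb up- and downstream). The set-level statistic is the
number of intervals overlapping ≥ 1 set gene. The null relocates each
interval to a uniformly random integer start on a random chromosome
(probability proportional to chromosome length), preserving interval
length, and — by default — re-draws until the relocated interval's gene
count is within ±1 of the original's (up to 100 tries), approximating a
gene-density-matched background; matching can be disabled. Empirical
p = (1 + #{perm ≥ obs})/(R + 1), R = 10,000 by default. The familywise
second stage resamples B = 1,000 pseudo-experiments from the stored
permutation null, computes each pseudo-experiment's best (minimum)
per-set empirical p, and corrects each set by the fraction of
pseudo-experiments whose best p beats it; a final elementwise max
enforces corrected_p ≥ empirical_p, which finite resampling can otherwise
violate by chance. Set sizes are filtered to 10–200 genes after
intersection with the annotation universe. Integer relocation starts make
the null exactly enumerable on toy genomes, which the tests exploit as an
oracle.

## The synthetic-data generator

`simulate_pair` draws, for each SNP, (z₁, z₂) from the bivariate normal
with marginal variances inflation1/inflation2 and covariance
`theoretical_overlap_cov(overlap)`, then mixes z-vectors within blocks
through the Cholesky factor of an AR-1 correlation matrix (parameter
ld_decay; the same mixing in both studies preserves the per-SNP
cross-study covariance), and finally adds a mean shift ± shared_effect_z
(random sign, same sign in both studies) at a designated random fraction
of SNPs. Defaults are the motivating study pair's conditions: study sizes
35,476/46,839 and 9,747/14,278 with 500 shared cases and 9,200 shared
controls, inflation 1.82 and 1.24, ld_decay 0 (the cross-trait lookup
operates on LD-pruned index SNPs, whose z-scores are treated as
independent), and shared_effect_z 4 — a non-centrality at which a shared
locus is detectable but not certain at α = 0.05, comparable to a
genome-wide-borderline association. All randomness flows from one seed.

What the simulator does **not** emulate: allele-frequency spectra,
genotype-level sampling noise, case-control ascertainment, population
stratification, or realistic LD (AR-1 is chosen for closed-form factors
and easy oracles). Passing calibration tests therefore show that the
correction is exact under its own model assumptions — the claim the method
itself makes — not that those assumptions hold in any particular real
dataset. `simulate_annotation` packs non-overlapping fixed-length genes
into per-chromosome lanes and samples uniform gene sets, optionally
seeding one set with the genes nearest a list of intervals to create a
genuinely enriched set.

## Numerical choices and problem sizes

* p ↔ z conversions use `scipy.stats.norm` survival functions; the exact
  binomial tail is summed in log space.
* LD matrices must be symmetric with unit diagonal; indefinite matrices
  (from rounding) are repaired by eigenvalue clipping and re-normalization
  at load, with a warning, at tolerance 1e-8.
* Report rows sort by corrected p, ties broken by chromosome then
  position (stable mergesort).
* Calibration and recovery tests use 1e5 simulated SNPs (Monte-Carlo
  standard errors ≈ 0.003 on variance-type quantities, ±0.0007 on a 5%
  rate), 10,000 replicates for the accuracy-vs-√r²pred check, and 400–4,000
  permutations in the gene-set tests; each such test runs in seconds.
* The whole pipeline is deterministic given the config and seed; a frozen
  copy of the resolved config is written next to every run's outputs.

## Known limitations

* The overlap covariance formula assumes both studies analysed a 1-df
  association test on the same trait-coding convention; covariances from
  subtler designs (family-based, mixed models) are out of scope.
* The LD-score intercept estimator is plain OLS without the weighting or
  block-jackknife standard errors of full LD-score regression software.
* Gene-count matching in the relocation null is an approximation to
  density-matched backgrounds; with `max_relocation_tries` exhausted the
  last draw is accepted, which can slightly dilute matching on extreme
  intervals.
* Strand-ambiguous (A/T, C/G) SNPs cannot be resolved from summary data;
  they are flagged and retained by default, which is auditable but leaves
  a potential sign error to the caller's judgement.
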