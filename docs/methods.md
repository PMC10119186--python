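# Methods

This note documents the models, the estimators, the numerical choices, and
the limits of what the synthetic benchmarks demonstrate.

## Synthetic cohort model

Common ancestry markers follow a Balding-Nichols two-population model:
ancestral frequencies p ~ Uniform(0.05, 0.95), population frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F) at divergence F (default FST = 0.1, a
founder-population scale), clipped to [0.01, 0.99].  Rare exonic sites use
a log-uniform ancestral minor allele frequency on [1e-4, 5e-3] so the
MAF ≤ 0.01 rarity rule is exercised on both sides, with ~1% of sites
deliberately placed on [0.008, 0.02] to straddle the cutoff.  Rare-site
divergence is a log-normal frequency perturbation with scale √F rather
than the Beta draw: at these frequencies the Beta's shape parameter is
≪ 1 and nearly every site would be fixed for the reference allele in a
cohort of thousands, destroying the intended spectrum.  Markers are
independent; realistic LD haplotype structure is out of scope (the PRS
stage builds LD only through its reference-panel windows).

Genotypes are Binomial(2, q·p_A + (1−q)·p_B) given each sample's admixture
fraction q, with configurable missingness.  Variants are dealt to genes in
contiguous balanced blocks.  Annotations draw consequence classes (60%
from the 12-class high-impact whitelist by default), CADD ~ Gamma(4, 5),
per-gene MSC cutoffs ~ Uniform(5, 25) (5% missing), GDI log-normal with
15% of genes above the 13.34 disease-gene bound, and a 2% blacklist.
Risk genes are forced onto the qualifying path so spiked signals survive
filtration — which is what a true causal high-impact variant would do.

Phenotypes follow a dominant carrier-level logistic model: carrying ≥ 1
qualifying allele in any risk gene multiplies disease odds by the
configured odds ratio (default 3), with the intercept solved by Brent's
method to hit the target prevalence (cases/(cases+controls)).  Each risk
gene's variant frequencies are set so its aggregate carrier fraction is
10% by default (k variants at f with 1−(1−f)^{2k} = 0.10).  A per-allele
(additive) option exists behind a flag.  The carrier architecture is a
stand-in, not an inference about the real cohort's architecture.

One integer seed expands to per-stage child seeds through
`SeedSequence([seed, crc32(stage)])`; fixing the seed fixes every artifact.

## Ancestry estimation

The estimator is supervised: reference panels fix the two populations'
allele frequencies and each sample's fraction q maximizes the binomial
likelihood over q ∈ [0, 1].  This replaces an unsupervised K=2 structure
run — with the reference panel included, the unsupervised solution is
essentially anchored to the panel anyway, and the supervised form is
deterministic, convex (the log-likelihood is concave in q), and testable.
The maximizer is found by safeguarded vectorized Newton iteration
(bracketed bisection fallback, tolerance 1e-6).  Flat likelihoods
(p_A = p_B everywhere) return q = 0.5 with a flag; samples with < 50
called markers are flagged unreliable.

Assignment takes the minimum reference-panel q as the cutoff (boundary
inclusive).  A second round re-estimates the target population's allele
frequencies empirically from reference + retained samples and re-applies
the updated minimum-reference cutoff — the analogue of re-running the
structure analysis on the retained subset, and the mechanism by which the
cutoff can rise between rounds.  Assignment is idempotent once stable.

At 5,000 markers and FST 0.1 the estimator's standard error is ≈ 0.03, so
individual boundary samples can land below 0.95 even when drawn at q = 1;
recovery claims are therefore about cohort RMSE and high quantiles, not
every sample.

## Quality control and the high-impact filter

Hardy-Weinberg uses the exact conditional test (full enumeration of the
heterozygote-count distribution by recurrence), computed in controls when
a phenotype is available — standard practice that avoids discarding true
risk variants out of equilibrium in cases.  Differential missingness is a
per-variant Fisher exact test on called/missing × case/control counts.
Kinship is the within-pair robust estimator
φ = (N_Aa,Aa − 2N_AA,aa)/(N_Aa,i + N_Aa,j) restricted to jointly called
markers (0.5 duplicates, 0.25 parent-offspring, ~0 unrelated); the
higher-missingness member of any pair above 0.185 is dropped.  Zero-MAD
metrics skip the outlier rule; cohorts under 10 samples skip MAD rules.

The six filter rules are pure per-variant predicates, so the survivor set
is order-independent and monotone in every threshold; attrition is
reported sequentially and must sum back to the input count.  Boundary and
missing-data policy: MAF ≤ 0.01 inclusive; missing reference MAF falls
back to the cohort frequency; missing MSC falls back to a configurable
CADD ≥ 15; missing GDI passes.  Coordinates are 1-based VCF throughout;
BED masks are 0-based half-open and converted at the I/O boundary.
Multiallelic records are split one-per-alternate with other alternates
recoded to reference, their AD depths folded into the reference depth, and
IDs regenerated as chrom:pos:ref:alt.

## Gene-level association

The carrier burden test is the 2×2 chi-squared without continuity
correction (both options exposed); zero cells take the Haldane-Anscombe
0.5 correction with a flag; all-carrier/no-carrier tables are degenerate
and produce no p-value.

The variance-component test forms the score statistic
Q_ρ = (1−ρ)‖Z_cᵀr‖² + ρ(1ᵀZ_cᵀr)² with Beta(MAF; 1, 25) weights,
covariate-adjusted genotypes Z_c, and residuals r from the logistic null
model.  ρ = 1 is evaluated at 0.999 throughout the omnibus machinery so
the min-p combination stays well-defined.  Per-ρ tail probabilities use a
moment-matched chi-square surrogate.  Two regimes:

- **Asymptotic** (`small_sample=False`): the eigenvalue mixture of
  R_ρ^{1/2} ZᵀP₀Z R_ρ^{1/2} with 4-moment (Liu-type) matching, and an
  optional Lugannani-Rice saddlepoint for the far tail.  Near the
  distribution mean the saddlepoint degenerates and falls back to the
  moment surrogate.
- **Binary small-sample** (default): rare-variant kernels with minor
  allele counts in the single digits make the asymptotic mixture
  mis-calibrated at the center (its median p ran ≈ 0.45 under a true
  null, λ_GC ≈ 1.27, while permutation gave ≈ 1.0).  The surrogate
  therefore uses the exact quadratic-form variance under independent
  Bernoulli residuals, 2Σλ² + Σᵢ Mᵢᵢ²·v(1−6v), and degrees of freedom
  from the kurtosis of 500 shared parametric-bootstrap residual draws.

The grid minimum p is combined by the standard one-dimensional integration
against the χ²₁ mixing variable, evaluated with a 128-node Gauss-Legendre
rule under the substitution x = u² (removing the χ²₁ density singularity).
In the distribution's center — where the integration's surrogate error is
the only remaining bias — the omnibus p is replaced by its empirical
bootstrap calibration P(min-p* ≤ min-p), which is well-resolved there
(switch point 10/B); the analytic value is kept in the tail where
bootstrap resolution runs out.  A single-variant block collapses to the
weighted score test for every ρ.

λ_GC is median(χ²-quantile of p)/median(χ²₁).  On a single null cohort
λ_GC varies ±~0.1 across seeds because all genes share one phenotype
realization; the calibration benchmark pools eight independent null
cohorts (≈ 5,600 gene tests) to average this out.

The phenome-wide scan keeps phenotypes with ≥ 100 cases, samples controls
1:10 without replacement (seeded) after removing case overlap, and adjusts
for the first two principal components.

## Distance-based prioritization

D_candidate is the mean distance from a candidate to the known set with
self-pairs excluded (a zero diagonal would mechanically deflate the
baseline); candidates that are themselves known genes stay in the
candidate list with their self-pair dropped.  The set-level statistic is
the nested mean-of-means, which coincides with the flat pair mean when the
known set is fixed and no pairs are missing (asserted in tests).
Retention is strict: D_candidate < D_known.  The resampling empirical P is
count/iters with ties counted as not-lower; the (count+1)/(iters+1)
variant is exposed on the result object.  The resampling pool defaults to
all genes entering the gene-level scan.  Clustering is average-linkage
agglomerative (no linkage is canonical for this use; average linkage is
robust to the block structure the generator produces), with Newick export;
the intermixing score handles distance ties fractionally so an
exchangeable matrix scores exactly the known-gene base rate.

A core candidate's distances to the known set follow the same
distribution as the known set's internal distances, so retention of core
candidates sits near one half by construction; what grows with the
core/background gap is the contrast against background candidates (→ 0
retained) and the resampling significance of a core-drawn candidate set.

## Polygenic risk scores

Marginal effects are standardized by √(2f(1−f)) from the reference panel,
shrunk under a point-normal prior (slab variance h²/(Mp)), and returned on
both scales.  The Gibbs sampler works over non-overlapping LD windows
(default 100 markers) from the reference panel; windows are independent,
so the sweep updates the same position of every window in one vectorized
step — sequential within a window, parallel across windows.  Default 300
iterations with one-fifth burn-in.  At p = 1 the closed-form infinitesimal
solution (R + (M/Nh²)I)⁻¹β̂ is used (and the sampler matches it within
Monte-Carlo tolerance in tests).  h² may be supplied or crudely estimated
as M(mean χ² − 1)/N̄ clipped to [0.01, 0.9].  Strand-ambiguous variants
are removed; reference-allele effects are sign-flipped onto the alternate.

Classification uses a random forest (500 trees, default depth — fixed and
recorded) on the seven grid scores with stratified seeded 10-fold CV and
out-of-fold AUC.  IDI is the four-mean formula.  The population-transfer
benchmark simulates a shared per-allele causal model in two populations at
FST 0.3 and compares AUC on a held-out target-population set using
matched- versus mismatched-population summary statistics; the claim tested
is directional (matched > mismatched on average), not any absolute AUC —
absolute discrimination is bound to the real cohort and is not reproduced
here.

## Benchmark problem sizes

The calibration suite uses eight pooled null cohorts of 1,500 cases/1,500
controls, 8,000 rare sites over 880 genes each; power uses twenty
replicates at 1,500/1,500 with 10,000 sites over 1,000 genes and five
spiked genes; distance calibration uses 200 meta-replicates of 500
resampling iterations on 50-gene matrices; the PRS contrast uses ten
replicates of 400 common markers with 1,000 training and 800 evaluation
samples.  These sizes give the tests stable operating characteristics
while keeping the full suite desk-scale.

## What the synthetic benchmarks do not show

Marker independence means the generator cannot probe LD-induced artifacts
(proxy associations, clumping behavior, LD-mismatched reference panels
beyond allele-frequency divergence).  The carrier-level disease model
cannot distinguish burden-style from dispersion-style signals the way real
architectures mix them.  Cohort-bound quantities from any real study —
specific gene p-values, variant counts, absolute AUCs, connectome
empirical P values — depend on controlled-access data and proprietary
resources and are not reproduction targets; the suite verifies worked
examples that are fully determined by stated inputs, plus operating
characteristics (calibration, power, recovery, direction) of each method.
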