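# ajburden

Rare high-impact variant case-control analysis for founder populations.

Exome studies of isolated populations — the motivating case is inflammatory
bowel disease (IBD) in Ashkenazi Jews, where a founder effect concentrates
rare deleterious alleles — need a pipeline that (1) genetically defines the
study population, (2) filters exome variants down to the rare, plausibly
damaging subset, (3) tests genes for case-control association by
aggregating those variants, (4) prioritizes candidate genes by biological
relatedness to known disease genes, and (5) asks whether the same variants
carry predictive signal as a polygenic risk score.  `ajburden` implements
that pipeline as a tested, reusable library with a synthetic cohort
generator, so every stage is exercisable end to end without access to any
controlled genotype data.

## What it computes

**Ancestry** (`ajburden.ancestry`) — markers are pre-masked (MAF > 0.02,
call rate > 95%, A/T-C/G pairs dropped) and LD-pruned (sliding window
50/5, r² ≤ 0.2).  Each sample's target-population fraction *q* maximizes
the supervised two-way admixture likelihood

    ℓ(q) = Σ_m log Binomial(g_m; 2, q·p_A,m + (1−q)·p_B,m),

with the reference panels fixing the ancestral frequencies p_A, p_B.
Samples are assigned when *q* reaches the minimum fraction observed in the
reference panel, with a second refinement round that re-estimates panel
frequencies from the retained set.  PCA on standardized genotypes
validates the assignment and supplies association covariates.

**Filtering** (`ajburden.qcfilter`) — variant and sample QC (depth/quality
means, call rate, exact Hardy-Weinberg in controls at P < 1e-6,
differential case/control missingness at P < 1e-5, 4-MAD sample metric
outliers, KING-style robust kinship > 0.185), then the six-step
high-impact filter: consequence whitelist, effective MAF ≤ 0.01 (reference
population MAF with cohort fallback), CADD ≥ the gene's mutation
significance cutoff (MSC), gene damage index (GDI) < 13.34, and a variant
blacklist, with per-rule attrition accounting.

**Association** (`ajburden.assoc`) — per-gene carrier collapsing with the
2×2 chi-squared burden test, and an optimized variance-component test
(SKAT-O style): Q_ρ = (1−ρ)·Q_SKAT + ρ·Q_burden over the grid
ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}, Beta(1,25) MAF weights,
covariate-adjusted logistic null model, a binary small-sample moment
adjustment, and min-p combination by one-dimensional integration.  Plus
per-variant logistic regression, λ_GC inflation checks, Bonferroni
thresholds, and a gene-level phenome-wide scan with 1:10 seeded control
sampling.

**Prioritization** (`ajburden.hgc`, `ajburden.rank`) — biological-distance
statistics on a gene×gene connectome: a candidate's mean distance
D_candidate to the known gene set, the known set's internal baseline
D_known, strict-inequality retention, a resampling empirical P
(#{D_random < D_observed}/iterations), and average-linkage clustering with
an intermixing score.  Pathway-method outputs are combined by strict
intersection, a known-gene importance score, and the joint top-10% rule.

**Risk scores** (`ajburden.prs`) — point-normal (spike-and-slab) shrinkage
of GWAS effects with windowed LD from a reference panel (Gibbs sampler;
closed-form infinitesimal solution at p = 1), one PRS per prior fraction in
(1, 0.3, 0.1, 0.03, 0.01, 0.003, 0.001), a random-forest classifier scored
by stratified 10-fold cross-validated AUC, and the integrated
discrimination improvement (IDI) between nested models.

**Synthetic cohorts** (`ajburden.synth`) — Balding-Nichols two-population
common markers, log-uniform rare-variant spectra with deliberate
rarity-cutoff straddlers, annotation/metric/blacklist tables with every
filterable attribute, carrier-model logistic phenotypes with risk alleles
spiked into designated genes, core-proximate distance matrices, and
score-regression summary statistics — all reproducible from one seed.

## Worked example

```python
from ajburden import assoc, synth

spec = synth.SimSpec(n_cases=1500, n_controls=1500, n_markers_rare=10_000,
                     n_genes=1000, risk_carrier_or=3.0,
                     risk_carrier_freq=0.10, seed=100)
study = synth.generate_study(spec)
qual = study.annotation_full[
    study.annotation_full.variant_id.isin(study.qualifying)]
blocks, _ = assoc.collapse_by_gene(qual, study.genotypes)
results = assoc.gene_scan(blocks, study.phenotype)
print(results.head(3)[["gene", "carriers_case", "carriers_control",
                       "or_carrier", "p_skato"]])
print("Bonferroni threshold:",
      f"{assoc.bonferroni_threshold(len(results)):.2e}")
```

prints (seed 100):

```
 gene  carriers_case  carriers_control  or_carrier      p_skato
G0003            186                81    2.576202 1.218767e-17
G0001            204               108    2.109011 8.366507e-13
G0002            190                91    2.333453 1.304616e-12
Bonferroni threshold: 6.26e-05
```

The five genes carrying spiked risk alleles (`G0001`–`G0005`) occupy the
five smallest p-values of the 799 genes tested; observed carrier odds
ratios near 2-2.5 reflect the dominant carrier model at odds ratio 3
after case-control sampling at 50% prevalence.  The same machinery reproduces the reference carrier-set
worked example: carriers reconstructed from 15.74% of 1,734 cases and
9.26% of 2,719 controls give OR = 1.83, P ≈ 9e-11 by 1-df chi-squared.

A CLI mirrors the stages: `ajburden simulate|ancestry|filter|assoc|hgc|rank|prs`
(see `ajburden --help`).

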