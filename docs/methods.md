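# Methods

`legacyscope` reimplements the statistical core of a precipitation-legacy
study design: soils collected along a steep precipitation gradient carry a
persistent imprint of their historical water regime, and that imprint is
traced from soil chemistry and community composition through host gene
expression to plant drought phenotypes. Every analysis here runs on
synthetic data with recorded ground truth, so each stage is validated by
parameter recovery rather than by comparison to any deposited dataset.

## The emulated study

A six-site gradient (default 400–1000 mm/yr, evenly spaced) defines the
*legacy* factor: the three driest sites are "dry legacy", the three wettest
"wet legacy" (the split is by precipitation rank; no numeric cutoff exists
in nature either). Within each site, samples cycle through a fully factorial
conditioning design — conditioning water (drought/watered) × conditioning
host (plant/none) × test-phase water (drought/control) — so that eight
replicates per site cover the 8 cells exactly once.

## Synthetic generators (`synthgen`)

All generators draw from named child streams of one global seed
(`SeedSequence([seed, crc32(name)])`), so each stage is bit-reproducible
independently of call order. Counts use the NB2 parameterization
Var = μ + αμ², matching the GLMs fit downstream.

| Generator | What it emulates | Key defaults and why |
|---|---|---|
| `gen_community` | taxon counts over the gradient | 20 of 200 taxa are markers with log-mean slope ±1 per sd precipitation; NB dispersion 0.3 and 10% structural zeros are typical of shotgun taxon tables; depth 50,000 keeps candidate taxa well above the prevalence filter |
| `gen_expression` | root transcriptome counts | baseline means log-normal (median ~200), per-sample size factors log-normal (σ=0.2), NB dispersion 0.1 — a quiet, deeply sequenced RNA-seq experiment; planted drought log2FCs of ±2 per gene set |
| `gen_traits` | 63 plant traits | multiplicative structure: drought scales means by 0.7, dry-legacy inoculum stabilizes the first 6 traits by a further 1.2× under drought; log-normal noise σ=0.15 |
| `gen_icpms_run` | ICP-MS runs | reference record at position 0 and after every 9 samples; observed = truth × (1 + slope·position); sample intensity encodes conc·dry_weight/dilution + blank so the full correction chain inverts exactly at zero noise |
| `gen_genotypes` | strain-level SNPs from pooled reads | dosage = Binomial(DP, p)/DP with DP ~ Poisson(15) — allele *frequencies*, not diploid calls, because the reads come from a community; 12 latent strain-admixture factors (loading sd 0.025) create the genome-wide structure that PC correction removes; site-level drift is mild (logit sd 0.01) |

The gene-set patterns planted by `gen_expression` (drought response per
legacy group) are: I wet-down only, II wet-up only, III dry-down only, IV
dry-up only, V same sign with a 4× magnitude difference, VI opposite signs.
Sets III and V complete the sign-pattern taxonomy by symmetry with the
explicitly described sets.

**What the generators do not emulate:** sequence reads and their biases,
phylogenetic correlation among taxa, gene–gene correlation, trait–trait
correlation beyond what the shared factors induce, linkage disequilibrium,
and real ICP-MS matrix effects. Passing tests therefore demonstrate that the
estimators recover the parameters of these idealized processes — not that
they would behave identically on field data, where all of the above are
present.

## Elemental analysis (`icpms`)

Drift correction follows the pooled-reference scheme: linear interpolation
between successive reference records (on record position, not clock time)
yields a theoretical reference at each position, and every record is scaled
by `ref_first / ref_theoretical(position)`. Records before the first or
after the last reference use the nearest reference (constant extrapolation)
— linear extrapolation would be unstable and a reference opens every run
anyway. Multi-run sets are bridged by rescaling each corrected run so its
first reference matches the first run's first reference; runs are ordered
canonically by run id so bridging is order-invariant. Concentrations are
`max(raw − blank, 0) × dilution / dry_weight`; negative blank-subtracted
values are floored at zero and logged.

## Ecological statistics (`ecostats`)

- **PERMANOVA** partitions the total sum of squared distances sequentially
  (type I) in formula order via the Gower-centered inner-product matrix and
  hat matrices of nested model matrices; pseudo-F uses the full-model
  residual. P values permute the distance matrix rows/columns simultaneously
  and use the +1 correction, so P ∈ [1/(n_perm+1), 1] always.
- **β-dispersion** embeds samples by PCoA keeping negative eigenvalues;
  squared centroid distances subtract the imaginary-axis components, and the
  one-way F on the distances is tested by label permutation.
- **Partial constrained ordination (CAP/RDA)** residualizes the response and
  the constraints on the condition model matrix, then decomposes the fitted
  values; permutation tests shuffle reduced-model residuals (Freedman–Lane).
  Constraint columns absorbed by the conditions are reported as aliased
  rather than silently dropped. Single-level condition columns are ignored.
- **Rarefaction** is seeded subsampling without replacement to the minimum
  column sum. CLR uses a 0.5 pseudocount by default.

## Differential analysis (`degenes`)

Per-feature NB2 GLM with log link and log size-factor offsets (median-ratio
by default, CPM for sparse matrices). Dispersion is estimated per feature by
Cox–Reid adjusted profile likelihood (penalty −½ log det XᵀWX) with a
moments fallback; the adjustment matters — unpenalized profile ML
underestimates α enough to push Wald CI coverage below 93% at 12 samples
per group. There is no empirical-Bayes shrinkage of dispersions or fold
changes; calibration is demonstrated by simulation, not by matching any
particular reference implementation. CIs are estimate ± 1.959964·SE on the
log2 scale.

The interaction classifier takes the drought log2FC and 95% CI separately
for dry- and wet-legacy plants (from the `legacy * test_water` model) and
calls an interaction only when the two CIs are entirely disjoint — a
deliberately conservative rule (two disjoint 95% CIs imply far less than 5%
false positives under equal true effects). A group is "null" when its CI
contains 0; the sign pattern assigns the gene set. Null status comes from
the CI, not from a q-value, so the classifier is self-contained.

## Mediation (`mediation`)

Legacy-sensitive genes are the union of legacy main-effect hits (BH q <
0.05) and CI-rule interaction hits. Their CPM/TPM-normalized expression is
summarized by non-metric MDS of Bray–Curtis distances: iterative
majorization (Guttman transform) alternating with isotonic regression of
disparities (primary/averaging ties), minimizing Kruskal stress-1; start 1
is the PCoA configuration, further starts are seeded random, and the final
configuration is PCA-rotated. Stress-1 is monitored each iteration and the
previous configuration is kept if renormalization ever ticks it upward, so
the reported trace is monotone.

Mediation uses the two linear models `M = α + aT` and `Y = β + bM + c′T`;
ACME = a·b, ADE = c′, total = a·b + c′ (an identity in the linear case,
checked to 1e-8). Uncertainty comes from a nonparametric percentile
bootstrap over samples — simpler to verify than quasi-Bayesian draws and a
consistent estimator in the same settings. Proportion mediated is reported
signed (ACME/total), so a mediator acting against the direct effect yields
a negative proportion.

## Drought-susceptibility index (`sindex`)

S = trait_drought / mean(trait_control), with the control group defined by
inoculum legacy × conditioning group by default (the grouping is a
parameter). Trait selection ranks traits by permutation importance of a
seeded random-forest classifier of legacy, keeps the top 10 and drops the
lower-ranked member of any pair with |r| ≥ 0.7. The legacy effect on S is
estimated by a random-intercept model over conditioning groups; when the
estimated intercept variance is at or near the boundary (ICC < 5%) the
model is refit as fixed effects `S ~ legacy + cond_group`, with adjusted
means averaging conditioning groups with equal weight. An optional response
transform (identity/sqrt/log/exp) can be chosen by residual normality.
Outliers are flagged by a 3×IQR rule per trait — an automated, reproducible
stand-in for visual screening.

**Known limitation:** S values within a control group share the same
denominator, which induces positive correlation that a conditioning-group
random intercept only partially absorbs. Null-calibration of the legacy CI
is therefore demonstrated under the model's own assumptions; with shared
denominators the CI is somewhat anticonservative (~90% at the default
design size when grouping at the denominator level).

## Genotype–environment association (`gea`)

Genotypes are per-sample alternate-allele dosages in [0, 1]. Filters follow
the standard thresholds (QUAL > 20, MAF > 0.01, missingness < 50%, depth ≥
10 per call, applied as per-call masking before the missingness test; the
depth bound is inclusive). Sample structure is summarized by the top 10 PCs
of the mean-imputed dosage matrix; each SNP's residual association with the
environment (partial correlation given the PCs) gives a t statistic, and
the family-wise threshold is the 95th percentile of the maximum |t| over
permutations of the environment vector. For designs where the environment
is constant within sites and site-level structure is strong, `permute_by=`
shuffles the site-to-environment assignment instead — the exchangeable unit
in that regime; the default remains sample-level permutation, which is
calibrated under the mild-site-drift generator defaults.

FST uses the Hudson frequency form (p₁−p₂)² / (p₁(1−p₂) + p₂(1−p₁)) — the
finite-sample haplotype-count correction does not apply to pooled
frequencies — aggregated as a ratio of averages; with more than two groups
the pairwise numerators and denominators are averaged. AMOVA Φ comes from
the among/within decomposition of squared allele-sharing distances with a
group-label permutation P.

## Marker taxa (`biomarkers`)

Candidates must exceed both a mean relative abundance threshold (default
0.01; the Results-style 0.001 reading is available as a parameter — the two
published figures are mutually inconsistent and the choice is deliberately
exposed) and 20% prevalence. The leading PCs of the z-scored elemental
profile (smallest set exceeding 80% cumulative variance) plus porosity
adjust five candidate models: Poisson, NB, zero-inflated Poisson,
zero-inflated NB (inflation on the adjustment covariates), and a Gaussian
linear regression. The AIC-minimal converged candidate is selected; the
precipitation term is tested by likelihood ratio (count models) or partial
F (linear), with BH correction across taxa.

The adjustment enters as free covariates by default. The published formula
notation ("offset(porosity)") read literally — covariates entering with a
fixed coefficient of 1 after z-scoring — is available via
`adjustment="offset"`, but each such term injects a full standard deviation
of extraneous variation into the linear predictor, which destroys power; we
treat the notation as shorthand for adjustment rather than as a literal
offset.

Two caveats are inherent to the published procedure and preserved here: AIC
comparison between discrete and Gaussian likelihoods is scale-mixed (the
Gaussian occasionally wins for near-normal counts), and an elemental profile
with near-equal eigenvalues puts the number of retained PCs at the boundary
of the 80% rule.

## Pipeline

`pipeline.run` executes simulate → icpms → ecostats → biomarkers → de →
mediate → sindex → gea from one validated YAML config; all stage seeds
derive from the global seed, and the manifest records parameters, seeds and
SHA-256 checksums of every output, so a config rerun is byte-identical. The
default demo sizes (120 taxa, 400 genes, 600 SNPs, 48 samples) complete in
about a minute on one CPU; they are chosen so a full run stays interactive
while every stage still has enough signal to recover its planted truth.

## Numerical conventions

- Permutation P values always use the +1 correction.
- z-scores use the n−1 (sample) standard deviation.
- 95% CIs use z = 1.959964 (Wald) or the t quantile (linear models).
- Zero-inflated fits run under a bounded iteration budget; non-convergence
  marks the candidate unavailable rather than failing the taxon.
- Isotonic regression uses primary (averaging) tie handling.
- Seeds derived from the global seed stay below 2³¹.
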