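# legacyscope

Soil microbial communities carry a *precipitation legacy*: a persistent
imprint of their site's historical water regime that survives transplanting
into a common environment and alters how host plants respond to a later
drought. Quantifying that legacy takes a long chain of inference — raw
ICP-MS elemental runs must be drift-corrected, taxon tables screened for
precipitation-tracking markers while controlling for soil covariates, host
gene expression tested for legacy × drought interactions, those genes
summarized and fed into a mediation analysis of plant traits, trait
stability scored against well-watered controls, and strain-level variants
scanned for association with the gradient.

`legacyscope` implements that chain as a tested, seed-reproducible Python
library, exercised end-to-end on synthetic data with recorded ground truth,
for microbiome and plant–microbe researchers who want the statistical
machinery of such a study without its bespoke R scripts.

## What is inside

| Module | Purpose |
|---|---|
| `synthgen` | generates every input — gradient design, taxon counts, NB expression counts, traits, ICP-MS runs, SNP dosages — with the planted parameters recorded for recovery tests |
| `icpms` | reference-standard drift correction, multi-run bridging, blank/dilution/dry-weight normalization |
| `ecostats` | Shannon effective diversity (e^H), Bray–Curtis, PCoA, sequential PERMANOVA, Mantel, β-dispersion, partial constrained ordination (CAP/RDA), CLR, rarefaction |
| `biomarkers` | abundance/prevalence filters, elemental PCs, five-model (Poisson/NB/ZIP/ZINB/linear) AIC selection for precipitation markers |
| `degenes` | per-feature NB GLM with Wald tests and BH correction; group-specific drought responses; the disjoint-CI legacy × drought interaction classifier with gene-set labels I–VI |
| `mediation` | non-metric MDS (Kruskal stress-1), single and joint linear mediation with percentile-bootstrap ACME/ADE |
| `sindex` | S-index (trait_drought / mean(trait_control)), iWUE, random-forest trait selection with collinearity pruning, mixed/fixed legacy-effect models, trait RDA |
| `gea` | SNP filtering, allele-sharing MDS, PC-corrected genotype–environment scans with max-\|t\| permutation thresholds, Hudson F_ST, AMOVA Φ |
| `pipeline` | YAML-configured orchestration with a checksummed, byte-reproducible manifest |

The statistical core in one line each: marker taxa are the AIC-best of five
count models for `abundance ~ precipitation` adjusted for porosity and
elemental PCs; a gene interacts with legacy when its two drought log2
fold-change 95% CIs (dry- vs wet-legacy plants) do not overlap at all;
mediation decomposes the drought effect on a trait through an MDS summary
of legacy-sensitive genes as ACME = a·b, ADE = c′, total = a·b + c′; and a
SNP is gradient-associated when its PC-corrected \|t\| exceeds the 95th
percentile of the permutation max-\|t\|.

## Worked example

Plant legacy-structured expression, run the differential pipeline and
select the legacy-sensitive gene set:

```python
from legacyscope import synthgen, degenes, mediation

design = synthgen.gen_design(n_sites=6, n_reps=16, seed=42)
expr, truth = synthgen.gen_expression(
    design, n_genes=600, set_counts={"I": 25, "IV": 25},
    lfc=2.0, n_legacy_main=10, seed=42,
)
sf = degenes.size_factors(expr.counts, mode="median_ratio")
de_main = degenes.nb_glm_wald(
    expr.counts, expr.design,
    ["legacy", "cond_water", "cond_host", "test_water"],
    contrast="legacy[wet]", sf=sf,
)
responses = degenes.drought_response_by_legacy(expr.counts, expr.design, sf=sf)
calls = degenes.classify_interaction(responses)
selected = mediation.select_legacy_sensitive(de_main, calls)

print("main-effect hits:", (de_main["q"] < 0.05).sum())
print("interaction hits:", calls["interacting"].sum())
print("legacy-sensitive genes:", len(selected))
```

Output:

```
main-effect hits: 63
interaction hits: 55
legacy-sensitive genes: 68
```

Of the 50 planted interaction genes, 55 calls are made (49 planted plus a
few borderline assignments); the recovered set labels split as
`{IV: 25, I: 24, VI: 3, II: 2, V: 1}`. The first called gene reads
`lfc_dry = -0.05 [-0.29, 0.20], lfc_wet = -2.16 [-2.41, -1.91]` — drought
suppresses it only in wet-legacy plants, so it lands in set I. The
main-effect count exceeds the 10 planted main-effect genes because
interaction genes also shift the marginal legacy contrast, exactly as in a
real experiment.

The full demo pipeline (simulation through GEA, ~1 minute on one CPU):

```bash
legacyscope run --seed 1 --out demo_run
```

writes `taxon_counts.tsv`, `marker_taxa.tsv`, `interaction_calls.tsv`,
`mediation.tsv`, `s_index.tsv`, `gea_scan.tsv`, … and a `manifest.json`
whose checksums are identical on every rerun with the same seed.

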