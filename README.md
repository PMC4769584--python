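# bayesrc

Annotation-informed Bayesian mixture models for joint QTL mapping and genomic
prediction — an implementation of BayesR and its variant-class extension
BayesRC, together with the synthetic-data machinery, comparators (single-SNP
GWAS, SNP-BLUP/GBLUP) and evaluation statistics needed to study their
behaviour end to end without any external data.

It is written for quantitative geneticists and breeding-program analysts who
want to (a) estimate whole-genome variant effects and posterior inclusion
probabilities for a quantitative trait, (b) inject prior biology — variant
classes such as "nonsynonymous coding in candidate genes" — into the model,
and (c) quantify what that prior buys in discovery and prediction accuracy.

## Model

The trait is modelled as

    y = X b + Z a + W v + e

with fixed effects **b**, optional pedigree polygenic values
**a** ~ N(0, **A** σ²ₐ), residuals **e** ~ N(0, **E** σ²ₑ) where
**E** = diag(1/w_j) carries per-record reliability weights, and a
centred/unit-variance dosage design **W** whose effects follow a
four-component mixture

    v_i ~ P₁·δ₀ + P₂·N(0, 0.0001 σ²_g) + P₃·N(0, 0.001 σ²_g) + P₄·N(0, 0.01 σ²_g).

BayesRC assigns every variant to an annotation class c and gives each class
its own proportions with a uniform Dirichlet prior, updated per Gibbs
iteration as **P**_c ~ Dir(**α**_c + **β**_c), where **β**_c counts that
class's variants per component. Classes enriched for causal variants learn
higher inclusion rates; with a single class the model is exactly BayesR
(bit-identical chains, same code path). The per-variant posterior inclusion
probability (PIP) is the fraction of post-burn-in iterations in which the
variant has a non-zero effect, averaged over replicate chains.

See `docs/methods.md` for the full conditional updates, priors, numerical
choices and limitations.

## Worked example

Simulate a two-population trait (h² = 0.6) whose 41 QTL all lie in candidate
gene regions, fit BayesRC with three annotation classes, and evaluate on the
held-out individuals:

```python
from bayesrc import (SimulationConfig, simulate_dataset, standardize,
                     fit_bayesrc, evaluate_prediction,
                     class_architecture_table)

cfg = SimulationConfig(
    n_per_population=(400, 400), n_validation_per_population=(100, 100),
    n_variants=2000, n_qtl_per_tier=(35, 5, 1), n_candidate_genes=20, seed=11,
)
ds = simulate_dataset(cfg)
g_tr = ds.genotypes.subset_individuals(ds.train_index)
g_val = ds.genotypes.subset_individuals(ds.val_index)
design = standardize(g_tr)

fit = fit_bayesrc(ds.training_phenotypes(), design, ds.classes, h2=0.6,
                  n_iter=2000, burn_in=1000, n_chains=3, seed=1,
                  genotypes=g_tr)

pred = evaluate_prediction(design.transform(g_val.dosages), fit,
                           ds.truth.genetic_values[ds.val_index])
print(f"accuracy = {pred.accuracy:.3f} +/- {pred.accuracy_se():.3f}, "
      f"bias slope = {pred.bias_slope:.2f}")
```

prints

```
accuracy = 0.958 +/- 0.001, bias slope = 1.06
```

i.e. the correlation between predicted and true genetic values in validation
is 0.958 (spread over the 3 chains shown as SD/√3), and regressing true on
predicted values gives a slope of 1.06 — close to 1, so predictions are
essentially unbiased. `class_architecture_table(fit, ds.classes)` summarises
the fitted architecture per class — here the candidate-gene class I keeps
65% of its members in non-null components against 27–43% elsewhere, the
enrichment signal the class prior is designed to pick up.

The same workflow is available from the shell:

```bash
bayesrc simulate --config sim.yaml --out sim
bayesrc qc   --geno sim.geno.tsv --maf 0.002 --classes sim.classes.tsv --out qc
bayesrc fit  --geno sim.geno.tsv --pheno sim.pheno.tsv \
             --classes sim.classes.tsv --covariates pop2 \
             --h2 0.6 --iters 40000 --burnin 20000 --chains 5 --seed 1 --out fit
bayesrc gwas --geno sim.geno.tsv --pheno sim.pheno.tsv --covariates pop2 --out gwas.tsv
bayesrc gblup --geno sim.geno.tsv --pheno sim.pheno.tsv --h2 0.6 --out gblup.tsv
```

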