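# cispred

Predicting gene expression from cis-SNP genotypes, and asking where the
predictable genes live on the genome.

Expression of many genes is heritable through nearby regulatory variants, so
a gene's expression level can be predicted from the SNPs within ±1 Mb of the
gene — the building block of transcriptome-wide association methods.  This
package implements and compares four standard genomic-prediction models for
that task, a simulator of genetic architectures to benchmark them under
controlled conditions, and enrichment statistics that test whether
well-predicted genes cluster in particular genomic regions or LD blocks.

## Models

For a centered expression vector **y** (n individuals) and cis-genotype
matrix **X** (n × p dosages):

* **Lasso / elastic net** — minimize
  `Q(β) = (1/n)‖y − Xβ‖² + Σⱼ P_λ(|βⱼ|)` with `P_λ = λ|β|` (Lasso) or
  `P_λ = λ(α|β| + (1−α)β²)` (elastic net, default α = 0.5), fitted by cyclic
  coordinate descent with λ chosen by k-fold cross-validation
  (`LassoCD`, `ElasticNetCD`).
* **Linear mixed model (LMM)** — `y = Xβ + ε`, `βⱼ ~ N(0, σ_b²σ_e²/p)`,
  equivalently a kinship model with `K = XXᵀ/p`; fitted by REML over the
  variance ratio σ_b² after one eigendecomposition, predicting by BLUP;
  heritability `h² = σ_b²/(σ_b² + 1)` (`LinearMixedModel`).
* **Bayesian sparse linear mixed model (BSLMM)** —
  `y = Xβ̃ + u + ε` with a spike-and-slab prior
  `β̃ⱼ ~ πN(0, σ_a²σ_e²) + (1−π)δ₀` on large effects and a polygenic term
  `u ~ N(0, σ_b²σ_e²K)`; fitted by Metropolis-within-Gibbs MCMC with the
  large effects and σ_e² integrated out analytically (`BSLMM`).

All three are scikit-learn-style estimators (`fit`/`predict`/`get_params`)
and compose with sklearn tooling.  Performance is measured as R², the
squared Pearson correlation between predicted and observed expression in a
held-out 20% of individuals.  A gene is called **predictive** when R² ≥ 0.05;
for a genomic region the **enrichment-fold** is

```
fold = (predictive genes in region / predictive genes in reference)
       ÷ (region length / reference length)
```

## Worked example

```python
import cispred

# a cis-region: 400 individuals x 500 SNPs with tight local LD, MAF >= 0.05
geno = cispred.simulate_genotypes(n=400, p=500, ld_rho=0.9, seed=1)

# scenario I: polygenic background + 15 large-effect SNPs, total PVE 0.5
cfg = cispred.ArchitectureConfig("I", total_pve=0.5, n_sparse=15, seed=1)
gene = cispred.simulate_gene(geno, cfg, replicate_seed=0)
print(round(gene.realized_pve, 10))          # 0.5 — PVE control is exact

tr, te = cispred.train_test_split(400, cispred.SplitSpec(seed=1))
model = cispred.BSLMM(n_burnin=2000, n_sampling=2000, random_state=1)
model.fit(geno.dosages[tr], gene.expression[tr])
r2 = cispred.r_squared(model.predict(geno.dosages[te]), gene.expression[te])
print(round(r2, 3))                          # 0.186 with these seeds
print(round(float(model.posterior_.pve_draws.mean()), 2))   # 0.63

# the MHC-style enrichment arithmetic: 45 of 179 predictive genes in an
# 8 Mb region of a 171 Mb chromosome
print(round(cispred.fold_from_counts(45, 179, 8, 171), 2))  # 5.37
```

The first two numbers say: the simulated gene's expression variance is
exactly 50% genetic, and on this replicate the hybrid model attains held-out
R² ≈ 0.19 (test R² is bounded above by the PVE and varies considerably
across replicates — the study engine averages 20 of them), with a posterior
PVE estimate bracketing the truth.  The 5.37 is the enrichment-fold of a region that
holds 25% of a chromosome's predictive genes in 4.7% of its length.

The same workflows are scriptable from a thin CLI:

```bash
cispred simulate --scenario I --n-sparse 15 --pve 0.5 --seed 1 --out-prefix sim/gene
cispred study --preset desk --out-prefix study/run     # scenario comparison
cispred fit --geno g.txt --snps s.txt --pheno e.txt --gene-bed genes.bed --out scores.tsv
cispred enrich --scores scores.tsv --region 6:26000001-34000000 \
               --chrom-lengths lengths.tsv
```

## File formats

* genotypes: BIMBAM mean-genotype TSV (`snp_id  A  G  dos₁ … dosₙ`) with an
  optional SNP location file (`snp_id  pos  chrom`), or standard VCF (DS or
  GT); export to VCF with hard genotypes.
* expression: one value per line, sample order of the genotype file.
* regions/LD blocks: BED (0-based half-open, converted on read); chromosome
  lengths: `chrom  length` TSV; per-gene scores: TSV with `r2_<method>`
  columns.
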