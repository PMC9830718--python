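# prana

Pseudo-value regression for **covariate-adjusted differential network
analysis** of gene co-expression data.

Classical differential-network (DN) methods ask whether the association
structure among genes changes between two conditions (e.g. current vs
non-current smokers), but most cannot adjust for clinical covariates such as
age — even though an apparent connectivity difference may be entirely
explained by a confounder. `prana` turns the network statistic into a
per-sample regression response so that ordinary covariates enter the model
directly. It is aimed at statisticians and computational biologists analysing
RNA-seq cohorts with a binary grouping variable and additional phenotype
columns.

## Method

For each group *z* with samples G_z (|G_z| = n_z):

1. **Association matrix.** Copula-transform each gene profile (ranks scaled
   to (0, 1)), then estimate mutual information for every gene pair with the
   ARACNE-style Gaussian-kernel plug-in estimator
   Î_jk = (1/n) Σ_i log f(g_ij, g_ik) / (f(g_ij) f(g_ik)).
2. **Total connectivity.** θ̂_k = Σ_j Î_jk, the column sum of the association
   matrix — a continuous analogue of degree centrality.
3. **Jackknife pseudo-values**, computed separately within groups:
   θ̃_ik = n_z θ̂_k^z − (n_z − 1) θ̂_k(i)^z, where θ̂_k(i)^z is recomputed from
   scratch on the data without sample i.
4. **Robust regression.** For each gene, regress the pseudo-values on the
   group indicator Z and covariates X by least trimmed squares (LTS):
   E[θ̃_ik | Z_i, X_i] = α_k + β_k Z_i + γ_k1 X_i1 + … + γ_kq X_iq.
5. **Testing.** H0: β_k = 0 via a t-test with reweighted-LTS standard
   errors; p-values are adjusted for multiplicity (Benjamini–Hochberg by
   default, empirical-Bayes screening optionally) and genes with adjusted
   p < α are called differentially connected (DC).

The package also ships the simulation engine used to validate the method: a
Gaussian-graphical-model network generator with three study designs (group
effect only; group + age effects; age as a pure confounder with unequal
age-category sampling between groups), an RNA-seq count mapper (inverse
empirical CDF of per-gene negative-binomial references), and a Monte-Carlo
harness reporting precision/recall/F1 against ground-truth DC labels.

## Worked example

Simulate a group-effect dataset (20 genes, 40 samples, two hubs silenced in
group 2) and run the pipeline on it:

```bash
prana simulate --scenario I --p 20 --n 40 --effect 0.1 --seed 3 --out sim/
prana run --expr sim/expr.tsv --pheno sim/pheno.tsv \
          --group group --covariates age --seed 4 --out res/
```

The `run` step prints

```
prana: 13/20 genes flagged DC (alpha=0.05, fdr=bh)
```

and writes `res/results.tsv` (one row per gene), the pseudo-value matrix, the per-group MI association matrices, and a reproducibility log. The first rows look like

```
gene_id   alpha    beta  gamma_1  se_beta  t_stat  p_value  q_value  dc_flag
     G1  4.9156 -2.9755  -0.0296   0.7620 -3.9048   0.0004   0.0013     True
     G2  3.4235 -3.9724   0.0307   0.7419 -5.3541   0.0000   0.0000     True
     G3 -0.3966 -0.8429   0.0290   0.6843 -1.2319   0.2265   0.2516    False
     G4  3.5971 -4.1747   0.0189   0.6880 -6.0678   0.0000   0.0000     True
     G5  2.9106 -2.6821   0.0067   0.6720 -3.9910   0.0004   0.0012     True
```

`beta` is the estimated change in total MI connectivity for group 2 relative
to group 1 after adjusting for age (negative here: the perturbed group lost
hub connectivity); `q_value` is the BH-adjusted p-value and `dc_flag` marks
genes significant at α = 0.05. Against the generator's ground truth
(`sim/truth.tsv`, 14 truly DC genes) the 13 flagged genes comprise 11 true
positives and 2 false positives.

The Monte-Carlo harness is available both as a library call
(`prana.run_simulation_study`) and as a command:

```bash
prana evaluate --scenario I --p 20 --n 40 --effect 0.1 \
               --replicates 200 --seed 1 --out metrics.tsv
```

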