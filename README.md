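# prismvote

Individualized polygenic risk prediction for genotype data that mixes
multiple populations, via the **Prism Vote** framework: instead of fitting
one predictor to a heterogeneous cohort, the cohort is split into ancestry
strata along a weighted principal-component score, a base prediction model
is fitted within each stratum, and every subject's final prediction is the
Bayesian composite

$$\Pr(Y=1\mid x_i)\;=\;\sum_{k=1}^{K}\Pr(Y=1\mid i\in k,\,x_i)\;\Pr(i\in k\mid x_i),$$

(with $E(Y\mid x_i)=\sum_k E(Y\mid i\in k,x_i)\Pr(i\in k\mid x_i)$ for
continuous traits).  The propensity $\Pr(i\in k\mid x_i)$ comes from
Bayes' theorem over a $\chi^2_1$ likelihood of the subject's distance to
each stratum center in the ancestry-score space:

$$\Pr(x_i\mid i\in k)=\Pr\!\big[\chi^2_1 > (w_i-c_k)^2/\hat\sigma_k^2\big],
\qquad w_i=\sum_{r\le q} a_r v_i^r,\quad a_r=\lambda_r\Big/\sum_{r\le q}\lambda_r .$$

Because each subject carries their own propensity spectrum, subjects with
identical risk alleles can receive different — individualized — risk
estimates.  Pooled ("reference") models lose accuracy as effect sizes
diverge across populations; the stratified composite does not, which is
what this package lets you measure.

It is aimed at statistical geneticists working with multi-ancestry or
admixed GWAS cohorts (PLINK or VCF genotypes, continuous or binary
phenotypes), and ships a fully synthetic two-population admixture
simulator so every analysis here can be reproduced without access to
controlled genotype data.

## Worked example

Simulate a two-population cohort (800 subjects per population, 800
variants, 240 causal, heritability 0.8, Fst 0.1) in which the two
populations share only 20% of their effect-size architecture
(η = 0.2), then compare Prism Vote (K = 2 strata, q = 10 PCs, ridge/GBLUP
base with REML shrinkage) against the reference method (the same base
model fitted once, controlling for the top 10 PCs) in a paired five-group
cross-validation:

```python
import prismvote as pv

cohort = pv.simulate_mixed_cohort(
    P=800, n_pop1=800, n_pop2=800, n_admixed=0, fst=0.1,
    n_causal=240, effect_model="correlated", eta=0.2, h2=0.8, seed=1,
)
report = pv.run_5gcv(
    cohort.genotypes, cohort.phenotypes,
    arms={"pv": {"K": 2, "q": 10}, "reference": {"q": 10}},
    folds=5, seed=1,
)
print(report.fold_metrics.round(3))
comp = pv.compare_arms(report)
print(f"improvement: {comp['mean_percent']:.1f}% (SD {comp['sd_percent']:.1f}%)")
```

Output:

```
           fold0  fold1  fold2  fold3  fold4
pv         0.652  0.596  0.665  0.651  0.651
reference  0.458  0.386  0.498  0.483  0.461
improvement: 41.3% (SD 8.3%)
```

Each row holds the Pearson correlation between observed and predicted
phenotype on the held-out fold.  At this level of cross-population effect
heterogeneity the pooled reference model reaches r ≈ 0.46, while the
stratified composite reaches r ≈ 0.64 — a 41% relative gain.  Re-run with
`eta=0.8` and the two arms nearly coincide: the advantage of
stratification grows as the populations' genetic architectures diverge.

The estimator interface composes with scikit-learn conventions:

```python
est = pv.PrismVote(K=2, q=10, base="ridge")
est.fit(G_train, y_train)                  # genotype counts, phenotype
detail = est.predict_detailed(G_test)      # final, per-stratum preds, propensities
```

`pv.select_k_q(G, y)` chooses the stratum count and PC depth by internal
cross-validation on the training data only, and
`pv.read_plink / pv.read_vcf / pv.qc_filter` handle standard formats and
the usual variant QC (call rate, Hardy–Weinberg, MAF).

## Command line

```bash
pv simulate --n-pop1 800 --n-pop2 800 --n-variants 800 --fst 0.1 \
            --h2 0.8 --seed 1 --out scratch/cohort
pv eval --bfile scratch/cohort --pheno scratch/cohort.pheno \
        --K 2 --q 10 --folds 5 --seed 1 --out scratch/cv
pv run  --bfile train --pheno train.pheno --test-bfile test \
        --select-kq --seed 1 --out scratch/preds
```

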