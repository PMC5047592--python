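# ceramic

Case-control genetic association testing for samples with related
individuals: a retrospective quasi-score test for binary traits that
adjusts for covariates on the logistic scale, models familial correlation
with an additive polygenic variance component, and uses partially missing
data through kinship-based genotype prediction.  For geneticists analyzing
family-enriched case-control samples (linkage-study families folded into
association panels, isolated populations, biobank pedigrees) where plain
logistic regression ignores relatedness and linear mixed models ignore the
binary trait.

## The model and statistic

Phenotypes follow a quasi-likelihood model specified by two moments,

    E(Y_i | X) = mu_i,  logit(mu_i) = X_i' beta,
    Var(Y | X) = Gamma^(1/2) (xi*Phi + (1-xi)*I) Gamma^(1/2),

where Phi is the pedigree kinship matrix (2*phi_ij off-diagonal, 1+h_i on
the diagonal), Gamma = diag(mu_i(1-mu_i)), and xi in [0,1] weighs additive
polygenic against independent variance.  Significance is assessed
*retrospectively*, under E0(G|Y,X) = X alpha, Var0(G|Y,X) = sigma_G^2 Phi,
which makes the level robust to phenotype-model misspecification.  With
genotypes observed on a set R and phenotypes/covariates on a set W, the
statistic

    T = (F' G_R)^2 / (sigma_G^2 * F' Phi_R F),
    F = M Phi_RW Z_W,   M = Phi_R^{-1} - Phi_R^{-1} 1 (1' Phi_R^{-1} 1)^{-1} 1' Phi_R^{-1},

is referred to chi-square(1).  It equals the score of the BLUP-imputed
genotypes against their retrospective variance and reduces exactly to
(Z'G)^2 / (sigma_G^2 Z'Phi Z) with complete data.  Two covariate-adjusted
MQLS-style companions (logistic residuals: MQLS-LOG; OLS residuals:
MQLS-LIN) share the missing-data machinery without a variance component.
See `docs/methods.md` for the full account.

## Worked example

Simulate one replicate of the default study design (60 sixteen-person
families plus 240 unrelated singletons, ascertained on >= 4 affected
members per family, with the standard missingness mechanism), then scan it:

```bash
cat > config.json <<'EOF'
{"trait_model": "logistic", "additive_frac": 0.6}
EOF
ceramic simulate --config config.json --seed 7 --out-prefix demo
ceramic -v scan --ped demo.ped --geno demo.geno.txt --pheno demo.pheno.tsv \
        --method ceramic,mqls-log,mqls-lin --out demo.scan.tsv
cat demo.scan.tsv
```

prints (the tested variant is an unlinked null SNP, so a non-significant
p-value is the expected outcome):

```
SNP     CHR  POS  N_GENO  N_PHENO  FREQ      STAT_CERAMIC  P_CERAMIC  STAT_MQLS_LOG  P_MQLS_LOG  STAT_MQLS_LIN  P_MQLS_LIN  FLAG
tested  0    0    622     763      0.218005  0.103353      0.747843   0.378078       0.538634    0.195048       0.658748    ok
```

`N_GENO` counts genotyped individuals (set R: 382 family members passing
the affected-relative genotyping rule plus all 240 unrelateds), `N_PHENO`
the individuals with complete phenotype and covariates (set W, here 324
genotyped members plus 439 ungenotyped ones who contribute through
genotyped relatives), and `FREQ` the kinship-weighted (BLUE) minor-allele
frequency estimate.  The `-v` log reports the genome-wide
variance-component estimate (here `xi = 0.545`) and, for multi-SNP scans,
the lambda_GC diagnostic and partition-cache statistics.  Single-SNP
effect estimation with standard errors (none for xi, by design; the fit
uses the genotype-informative subset, whose affected-enriched composition
can yield a much smaller xi than the scan's):

```bash
ceramic estimate --ped demo.ped --geno demo.geno.txt --pheno demo.pheno.tsv --snp tested
```

```
Parameter                 Estimate        SE
xi (VC parameter)          0.00736         -
gamma (SNP effect)         -0.1449      0.21
beta[0]                      -19.2       3.3
beta[1]                    0.02531    0.0046
beta[2]                      1.564      0.31
beta[3]                    0.07054     0.016
beta[4]                      0.379     0.046
```

Replicate studies of type-1 error or power (here 200 replicates of the
liability-threshold null scenario):

```bash
ceramic study --model threshold --additive-frac 0.4 --replicates 200 \
        --seed 1 --method ceramic --out rates.tsv
```

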