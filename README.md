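# metabotype

Unsupervised metabolic subtyping of obesity from routine clinical variables.

Obesity is metabolically heterogeneous: two patients with the same BMI can
differ radically in glycemic burden, insulin dynamics and comorbidity risk.
`metabotype` implements a clustering pipeline that partitions obese cohorts
into four reproducible metabolic subtypes from three variables derived from
an oral glucose tolerance test (OGTT) and a standard lab panel:

- **glucose AUC** (mmol/L·min) — trapezoidal area under the four-point
  (0, 30, 60, 120 min) OGTT glucose curve,
- **insulin AUC** (mU/L·min) — same for insulin,
- **uric acid** (μmol/L) — serum urate.

The four subtypes and their naming rule:

| subtype | meaning | deciding feature |
|---|---|---|
| MHO | metabolically healthy obesity | remainder |
| HMO-U | hypermetabolic obesity, hyperuricemia | highest uric acid of the rest |
| HMO-I | hypermetabolic obesity, hyperinsulinemia | highest insulin AUC of the rest |
| LMO | hypometabolic obesity (decompensated) | highest glucose AUC |

The pipeline is intended for biostatisticians and clinical-research teams who
want to reproduce, stress-test, or apply this subtyping on their own cohorts.

## What it does

1. **Feature derivation** (`metabolic_features`): trapezoid AUCs plus the
   standard insulin-sensitivity panel (HOMA-IR = g₀·i₀/22.5,
   HOMA-β = 20·i₀/(g₀−3.5), IGI = Δi₃₀/Δg₃₀, Matsuda WBISI =
   10⁴/√(g₀·i₀·ḡ·ī) with glucose in mg/dL, and the disposition indices
   HOMA-β/HOMA-IR and IGI×WBISI).
2. **AUC imputation** (`auc_imputation`): stepwise linear regression
   (partial-F inclusion at P < 0.05, elimination at P > 0.10) estimating the
   four-point AUCs from one-to-three measured time points, trained on a 70/30
   split of complete records.
3. **Subtype discovery** (`subtype_clustering`): per-sex z-normalization,
   then k-means (Lloyd, k-means++ starts, k chosen by maximum mean silhouette
   width) or two-step clustering (log-likelihood merge distance, Schwarz BIC
   for k), with the two sex sub-models pooled.
4. **Cross-cohort validation** (`cross_cohort_validation`): nearest-center
   assignment of new cohorts in the model's normalized space, optimal cluster
   matching, per-cluster one-vs-rest accuracy/sensitivity/specificity and
   Jaccard coefficients (mean Jaccard > 0.750 read as stable).
5. **Comorbidity statistics** (`comorbidity_stats`): sex- and age-adjusted
   odds ratios per subtype vs MHO (logistic regression, Wald 95% CI),
   chi-square tests, ANOVA/ANCOVA with Bonferroni-corrected contrasts.
6. **Synthetic cohorts** (`synthetic_data`): a generator calibrated to the
   published per-sex cluster centers and subtype prevalences
   (44/33/8/15%), with OGTT curves that integrate exactly to the drawn AUCs,
   optional missingness, and subtype-dependent comorbidity odds — so the
   whole pipeline runs and validates without patient data.

## Worked example

```python
import metabotype as mt

# a study-calibrated synthetic main cohort (n=882)
cohort, truth = mt.generate_cohort(seed=1)

fit = mt.fit_sex_stratified(cohort, algorithm="kmeans", seed=1)
print(fit.model.k, fit.model.labels)
print({s: round(100 * v, 1) for s, v in sorted(fit.partition.shares().items())})

verification, _ = mt.generate_cohort(mt.SyntheticConfig(n=300), seed=2)
result = mt.verification_run(fit.model, verification, seed=3)
print(round(result.report.mean_accuracy, 3), round(result.report.mean_jaccard, 3))
```

prints

```
4 ('MHO', 'HMO-U', 'HMO-I', 'LMO')
{'HMO-I': 6.5, 'HMO-U': 33.0, 'LMO': 16.2, 'MHO': 44.3}
0.997 0.991
```

i.e. silhouette-based selection finds the four-cluster structure, the pooled
partition reproduces the generating prevalences (44/33/8/15%) within
sampling error, and an independent clustering of a fresh cohort agrees with
nearest-center assignment to the main model almost perfectly (mean
per-cluster accuracy 0.997, mean Jaccard 0.991).

The same workflow is available from the shell:

```bash
metabotype simulate --n 882 --seed 1 --out cohort.csv
metabotype fit --cohort cohort.csv --algorithm kmeans --seed 1 --out model.json
metabotype assign --cohort cohort.csv --model model.json --out partition.csv
metabotype validate --cohort cohort.csv --model model.json --report report.json
metabotype stats --cohort cohort.csv --partition partition.csv --out aor.csv
```

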