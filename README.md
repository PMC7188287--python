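# gfrcompare

Validation toolkit for creatinine-based GFR estimating equations against
measured glomerular filtration rate (mGFR), written for nephrology and
clinical-chemistry researchers who compare estimating equations in
specific populations — the motivating case being kidney transplant
recipients one year after graft, where equation performance established
in ordinary CKD cohorts does not carry over.

## What it does

**Equations** (`gfrcompare.equations`). The four creatinine-based
estimators, all in mL/min/1.73 m² with plasma creatinine (PCr) in mg/dL:

- CKD-EPI (2009): sex-specific two-piece power law,
  `base · (PCr/κ)^α · 0.993^age` with knots κ = 0.7 (F) / 0.9 (M);
- MDRD (IDMS): `175 · PCr^−1.154 · age^−0.203 · [0.742 if female]`;
- Lund-Malmö Revised (LMR): `exp(X − 0.0158·age + 0.438·ln age)` with a
  sex-specific piecewise X(PCr), knots 1.7 (F) / 2.0 (M) mg/dL;
- Full Age Spectrum (FAS): `107.3 · (Q/PCr) · [0.988^(age−40) if age > 40]`,
  Q = 0.9 (M) / 0.7 (F) mg/dL.

The 1.159 multiplier historically applied to Black patients is
implemented but off by default (European-population recommendation).

**Reference mGFR** (`gfrcompare.clearance`). Urinary inulin UV/P
clearance (mean of timed periods) and iohexol plasma slope-intercept
clearance (one-compartment fit of ln-concentration on time, clearance
= dose·k/C₀) with Bröchner-Mortensen correction, DuBois body-surface-area
indexing to 1.73 m², and Passing-Bablok regression for cross-method
calibration.

**Agreement battery** (`gfrcompare.agreement`). For paired eGFR–mGFR
vectors: bias (mean difference), precision (SD of differences),
2.5%/97.5% limits of agreement, P30 accuracy, log-scale regression
RMSE, the total deviation index (TDI at 90% coverage), Lin's
concordance correlation coefficient (log scale) with its
strength-of-agreement bands, Deming regression, and Bland-Altman data.

**Diagnostics** (`gfrcompare.diagnostics`). Rank (Mann-Whitney) AUC and
2×2-table metrics — sensitivity, specificity, PPV, NPV, likelihood
ratios with interpretation bands — for detecting mGFR < 45
mL/min/1.73 m².

**Inference** (`gfrcompare.resampling`). BCa bootstrap confidence
intervals (default 2,000 replicates), Cochran Q + pairwise McNemar for
paired P30 comparison, paired bootstrap AUC comparison, and
Holm-Bonferroni family-wise error control (default α = 0.005).

**Synthetic cohorts** (`gfrcompare.cohort`). Seed-deterministic
generator emulating a transplant referral cohort (n = 395, mGFR
48.0 ± 14.2 on 13–108 mL/min/1.73 m², age 52.4 ± 13.8, 39.6% female)
with a multiplicative lognormal eGFR error and creatinine obtained by
numerically inverting a chosen "truth" equation — so the whole pipeline
can be exercised, and its answer known, without patient data.

**Pipeline + CLI** (`gfrcompare.pipeline`, `gfrcompare` command).
`simulate`, `estimate`, `clearance` and `compare` subcommands; `compare`
emits agreement/diagnostic/comparison tables (whole cohort and
mGFR <45 / ≥45 strata) with BCa CIs, Bland-Altman data files and a run
log, bit-reproducible for a given seed.

## Worked example

```python
from gfrcompare import (BootstrapConfig, CohortSpec, PatientRecord, RunConfig,
                        egfr_panel, generate_cohort, run_comparison)

rec = PatientRecord(id="example", age=52.0, sex="male", pcr=1.43, mgfr=48.0)
print({k: round(v, 1) for k, v in egfr_panel(rec).as_dict().items()})
# {'ckdepi': 55.9, 'mdrd': 51.9, 'lmr': 52.3, 'fas': 58.4}

cohort = generate_cohort(CohortSpec(seed=1)).to_frame().drop(columns=["true_egfr"])
bundle = run_comparison(RunConfig(bootstrap=BootstrapConfig(replicates=2000, seed=1)),
                        cohort=cohort)
cols = ["equation", "bias", "bias_low", "bias_high", "p30", "tdi", "ccc"]
print(bundle.agreement.query("stratum == 'all'")[cols].round(2).to_string(index=False))
```

```
equation  bias  bias_low  bias_high   p30   tdi  ccc
  ckdepi  4.88      4.11       5.69 87.34 32.21 0.85
    mdrd  1.25      0.51       1.97 94.94 27.48 0.87
     lmr  0.55     -0.17       1.22 96.96 25.05 0.89
     fas  6.41      5.61       7.10 79.75 38.13 0.77
```

The default synthetic cohort uses LMR as its generating equation with a
lognormal error of σ = 0.15, so LMR comes out nearly unbiased (+0.55
[−0.17; 1.22] mL/min/1.73 m², a BCa 95% CI straddling zero) with the
best P30 (97%), TDI (25% — 90% of its estimates fall within ±25% of
mGFR) and concordance, while the other equations show systematic bias
of up to +6.4 mL/min/1.73 m². The same run's diagnostic table reports
each equation's AUC (0.90–0.94 here), sensitivity/specificity and
likelihood ratios for detecting mGFR < 45 mL/min/1.73 m².

The same analysis from the shell:

```sh
gfrcompare simulate --n 395 --seed 1 --out cohort.csv
gfrcompare compare --input cohort.csv --seed 1 --out reports/
```

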