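# Methods

This note records the statistical model behind `gfrcompare`, the
numerical conventions it fixes, the design choices that were genuinely
open, and what the synthetic-data tests do and do not demonstrate.

## Estimating equations

All four equations take plasma creatinine (PCr) in mg/dL, age in years
and sex, and return eGFR in mL/min/1.73 m². Creatinine in µmol/L must
be converted explicitly (`convert_creatinine`, factor 88.4): the
package deliberately has a single internal creatinine unit so that a
unit mix-up fails loudly instead of silently scaling a result by ~88.

- **CKD-EPI (2009)**: `base · (PCr/κ)^α · 0.993^age` with
  (κ, base) = (0.7, 144) for women and (0.9, 141) for men; α is −0.329
  (F) / −0.411 (M) below the knot and −1.209 above it for both sexes.
  At the knot the power term is 1 regardless of exponent, so the two
  branches agree exactly.
- **MDRD (IDMS-traceable)**: `175 · PCr^−1.154 · age^−0.203 · 0.742^[female]`.
- **LMR**: `exp(X − 0.0158·age + 0.438·ln age)`. X is linear in PCr
  below the sex-specific knot (1.7 F / 2.0 M mg/dL, the mg/dL
  equivalents of 150/180 µmol/L) and logarithmic above it, with
  X = 2.50 (F) / 2.56 (M) at the knot from both sides. The sub-knot
  linear coefficients (0.0121, 0.00968) are defined per µmol/L of
  creatinine in the equation's source publication; this package
  multiplies them by 88.4 so they apply to mg/dL. Without that scaling
  the sub-knot branch is essentially flat and yields physiologically
  impossible estimates (≈30 mL/min/1.73 m² for a healthy young adult),
  and no creatinine value can reproduce a normal GFR.
- **FAS**: `107.3 · (Q/PCr)`, decayed by `0.988^(age−40)` after age 40;
  Q (0.9 M / 0.7 F mg/dL) is the median creatinine of a healthy
  population, so Q/PCr = 1 marks "average kidney function for a healthy
  adult" and the estimate equals the 107.3 constant.

The 1.159 multiplier for Black patients in CKD-EPI and MDRD is
implemented behind a flag and **off by default**, following the
recommendation against its use in European populations. Equations
accept any age > 0 but warn above 100 years (extrapolation);
`PatientRecord` enforces the adult (≥18) domain this package targets.

## Measured GFR

- **Urinary inulin**: UV/P per collection period, averaged over the 2–6
  periods of a water-diuresis protocol.
- **Plasma iohexol**: single-bolus, late-sample design (nominally
  120/180/240 min). `ln(conc)` is regressed on time by unweighted OLS
  (weighting schemes are out of scope); clearance is `dose·k/C₀`, the
  slope-intercept form of dose/AUC for a one-compartment model. A
  non-negative fitted slope is reported as degenerate kinetics, not a
  clearance.
- **Bröchner-Mortensen correction** for the missed distribution phase:
  `0.990778·CL − 0.001218·CL²` (standard adult coefficients; the
  correction is monotone and below identity over the physiological
  range, apex ≈ 406 mL/min). Coefficients are keyword-exposed.
- **Indexing**: DuBois BSA `0.007184·W^0.425·H^0.725` (kg, cm),
  clearance × 1.73/BSA.
- **Passing-Bablok** (original 1983 procedure) for cross-method
  calibration: slope = shifted median of the C(n,2) pairwise slopes,
  where slopes of exactly −1 are excluded, vertical slopes enter as
  signed infinities, and the median index is offset by the count K of
  slopes below −1; intercept = median(y − b·x). The estimated
  calibration line is *reported, not applied*: the pipeline treats the
  two reference methods as equivalent by default, and a user-supplied
  calibration can be applied upstream if desired.

## Agreement statistics

For pairs (eGFR, mGFR), differences d = eGFR − mGFR (positive =
overestimation):

- bias = mean(d); precision = SD(d) with n−1;
- limits of agreement: empirical 2.5th/97.5th percentiles of d by
  default (n ≥ 10), parametric bias ± 1.96·SD as an option — both are
  provided because printed LoA in validation studies are rarely
  explicit about which convention was used;
- P30 = % of |d| ≤ 0.30·mGFR, boundary inclusive;
- RMSE: root mean squared residual of OLS log₁₀(eGFR) on log₁₀(mGFR).
  The log scale is a deliberate choice: on the native scale the
  0.12–0.18 magnitudes such studies print would be impossible, while
  log-scale residual spread reproduces them; the scale is config-visible;
- **TDI** at coverage 90%: the empirical default is the 90%-quantile of
  |ln(eGFR/mGFR)| back-transformed to percent, `100·(exp(q)−1)`. Under
  the package's lognormal error model this estimates the same quantity
  as the parametric lognormal TDI
  `100·(exp(z₀.₉₅·√(µ²+σ²))−1)` (µ, σ from ln eGFR/mGFR), so the two
  modes cross-validate each other; a plain relative-difference
  convention (quantile of |d|/mGFR) is available but is *not*
  asymptotically equal to the parametric form, because e^ε−1 is
  asymmetric in ε;
- **CCC** (Lin): `2·s_xy / (s_x² + s_y² + (x̄−ȳ)²)` with n−1 moments,
  computed on ln pairs by default because the spread of d grows with
  GFR level; bands: >0.990 almost perfect, 0.950–0.990 substantial,
  0.900–0.949 moderate, <0.900 poor;
- **Deming** regression of eGFR (y) on mGFR (x) with error-variance
  ratio λ (default 1, orthogonal regression — no ratio is identifiable
  from one pair per subject);
- quantiles everywhere use linear interpolation of order statistics
  (numpy default, "type 7").

## Diagnostics

Positive class = mGFR < 45 mL/min/1.73 m²; positive test = eGFR below
the same cutoff (the only clinically named threshold; config-exposed).
AUC uses the Mann-Whitney rank form with ties ½ — identical to the ROC
of a fitted one-predictor logistic model, since the logit is monotone
in eGFR — and is not floored at 0.5. Empty 2×2 margins yield NaN flags;
a perfect test reports PLR = +∞. PLR bands: >10 large, 5–10 moderate,
<5 small.

## Resampling inference

- **BCa**: resample subjects (paired rows) with replacement;
  z₀ = Φ⁻¹(fraction of bootstrap statistics below the observed value,
  clipped to (1/(B+1), B/(B+1))); acceleration a from jackknife
  skewness; adjusted percentile endpoints. Degenerate bootstrap
  distributions give a zero-width interval with a warning; a
  bootstrap distribution with no finite values (e.g. PLR of a perfect
  test) gives NaN bounds with a pathological flag. Intervals failing
  to bracket their point estimate are flagged, not "fixed".
- **Cochran Q** on the subjects × equations within-30% indicator matrix,
  chi-square on k−1 df; all-constant rows contribute nothing, and a
  table with only such rows returns Q = 0, p = 1 with a warning (the
  methods never disagree, so there is no evidence of a method effect).
- **McNemar**: exact two-sided binomial at p = ½ when discordant pairs
  b+c < 25, chi-square (b−c)²/(b+c) without continuity correction
  otherwise; both forms forceable.
- **Holm-Bonferroni** step-down at α = 0.005 by default, applied within
  each metric family (P30 pairs, bias pairs, AUC pairs) separately;
  step-down adjusted p-values are also reported.
- **AUC comparison**: joint subject resampling preserving pairing;
  replicates missing a class are redrawn (cap 100) then dropped with a
  warning; two-sided p doubles the tail proportion of ΔAUC* beyond 0.
- Reproducibility: one root seed per run; per-statistic streams derived
  as CRC32-labelled `SeedSequence`s of (root, statistic, equation,
  stratum), logged for audit. Reports are byte-identical across reruns.

## Synthetic cohort generator

Marginals (defaults): mGFR ~ truncated Normal(48.0, 14.2) on [13, 108]
mL/min/1.73 m²; age ~ truncated Normal(52.4, 13.8) on [18, 100] y;
39.6% female; weight ~ N(70.2, 13.5) kg, height ~ N(167.0, 9.5) cm
(independent of mGFR — real anthropometry–GFR correlation is not
modelled); 79% iohexol / 21% inulin method labels. Truncation is by
rejection sampling (tail masses are small enough that exactness is
irrelevant).

Error model: the truth equation's estimate is `mGFR·exp(ε)`,
ε ~ N(0, σ²), default σ = 0.15. The multiplicative form makes the
spread of eGFR−mGFR grow with GFR level, the heteroscedasticity seen in
real validation data, and gives closed-form targets: the parametric TDI
converges to `100·(exp(1.645σ)−1)` (≈28% at σ = 0.15, the magnitude of
TDIs reported for transplant cohorts), and the multiplicative bias to
`e^{σ²/2}`. Creatinine is then obtained by inverting the truth equation
— every equation is strictly decreasing in PCr, so an 80-step bisection
on PCr ∈ [0.1, 20] mg/dL is exact to machine precision (the scalar
`invert_equation` uses Brent's method on the same bracket). Noise draws
that push the target outside the equation's attainable range are
redrawn with a capped retry count; at the default spec this is never
hit.

What passing tests show — and don't: with σ = 0 the generator's truth
equation reproduces mGFR exactly, so pipeline round-trip tests verify
the *computational* chain, not clinical performance; the generator has
no creatinine assay error, no non-GFR determinants of creatinine
(muscle mass, drugs), and treats the two reference methods as
interchangeable, so agreement figures from synthetic runs characterise
the chosen error model only.

The clearance-study generator works backwards from a requested total
(Bröchner-Mortensen-corrected) clearance: it inverts the BM quadratic
to get the one-compartment raw clearance, places C₀ = dose/V with
V = 250 mL/kg (extracellular-fluid scale for iohexol), and evaluates
the mono-exponential at the protocol times, optionally multiplied by
mean-one lognormal noise of a given CV. A noiseless study therefore
round-trips through the forward pipeline to 10⁻⁶ relative.

## Problem sizes and defaults

Bootstrap default 2,000 replicates at coverage 95%; pipeline examples
and tests use 200–2,000. Synthetic checks use n = 150–5,000 cohorts
(large-sample limits at n = 10⁴–10⁵), 1,000-repeat coverage
simulations at B = 2,000, and exhaustive oracles on instances of ≤ 15
subjects, sizes at which the exact enumerations are still instant while
sampling error is negligible for the properties asserted.

## Known limitations

- Creatinine-only: no cystatin-C or combined equations, no pediatric
  equations.
- One pair per subject; no repeated-measures agreement models.
- One-compartment plasma kinetics only; early-sample distribution-phase
  protocols are out of scope.
- The operating threshold for the diagnostic table equals the disease
  cutoff; no threshold optimisation or decision-curve analysis.
- MDRD's deviation from an LMR-generated cohort is sex-antisymmetric
  (men positive, women negative), so its *sex-pooled* mean bias on the
  default cohort mix is small (~+0.7 mL/min/1.73 m²) even though each
  sex is biased by ~2 mL/min/1.73 m²; pooled bias alone understates
  how distinguishable the two equations are.
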