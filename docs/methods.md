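# Methods

## Models

### Ecoenzymatic vectors

Per sample, the two log-ratio components are
`x = ln(bg + cbh) / ln(ap)` and `y = ln(bg + cbh) / ln(nag + lap + ue)`;
angle `= degrees(atan2(x, y))`, length `= sqrt(x² + y²)`.  Two conventions
are pinned by observable behaviour rather than by a library call signature:

- **Angle orientation.**  `x = y` gives exactly 45°; relative P investment
  (larger `x`) gives angles above 45° (P limitation); larger `y` gives angles
  below 45° (N limitation).  This removes the argument-order ambiguity of
  `atan2` across math libraries and spreadsheets.
- **Length formula.**  A widely printed variant of the length uses
  `ln(bg)/ln(ap)` (βG alone) for the P term while the angle pools βG+CBH on
  both axes.  The default here uses consistent pooled axes, so
  `length² = x² + y²` holds and length/angle describe the same vector; the
  printed variant is available as `strict_length=True` (CLI `--strict-length`)
  and is always strictly smaller whenever CBH > 0.

Since the components are ratios of logarithms, they are **not invariant to
unit rescaling** of the activities.  All activities are treated as
nmol g⁻¹ dry soil h⁻¹ and every pooled activity must exceed 1 in that unit;
values ≤ 1 are rejected at ingest rather than shifted, because any shift
would silently change the geometry.  Absolute angle values are therefore
conditional on the unit convention; treatment *contrasts* of the angle are
the meaningful output.

`tan(angle) = ln(Npool)/ln(AP)` follows directly from the definitions: the
angle responds only to the N- and P-axis log pools, not to the C enzymes.

The N:P activity ratio is computed as `(nag + lap + ue) / ap`.  This
constituent formula is an interpretation (the ratio circulates in results
narratives without a printed definition) and is flagged as such in the code.

### CUE_ST

`S_CN = (1/EEA_CN) · (B_CN / R_CN)` with `EEA_CN = bg/(nag+lap)`,
`B_CN = MBC/MBN`, `R_CN = DOC/TDN`; `CUE_ST = CUE_max · S/(S + K_N)`.

| constant | default | meaning |
|---|---|---|
| `CUE_max` | 0.6 | thermodynamic ceiling on growth efficiency |
| `K_N` | 0.5 | half-saturation of the stoichiometric scalar |

Both are configurable and echoed in every output row.  Analytic properties
relied on by the tests: `CUE_ST(K_N) = CUE_max/2` exactly; `CUE_ST` is
strictly increasing in `S` and bounded in `[0, CUE_max)`; it depends on DOC,
TDN, MBC, MBN only through their ratios.  `S = 0` returns CUE 0 (total on
the closed half-line) rather than an error.  Group-level CUE is the mean of
per-sample CUE_ST values, consistent with reporting means ± SE; computing
CUE from group-mean ratios is the rejected alternative.

### Carbon pools

`stock [kg C m⁻²] = SOC fraction × BD [kg m⁻³] × thickness [m]`.  The
interface takes a mass *fraction* and rejects values above 1 as un-converted
percents; the cohort schema stores `soc_pct` in percent and the table-level
helper divides by 100 at the boundary.  Microbial biomass is the plain
fumigated-minus-non-fumigated difference with **no** extraction-efficiency
divisor (`k_EC`/`k_EN`); small negative differences are clamped to 0 and
flagged `below_detection` instead of raising, since they arise from
measurement noise near the detection limit.  No oxidation-efficiency or
stone-content corrections are applied.

### Inference stages

- **Group comparison.**  Shapiro–Wilk on ANOVA residuals; square-root
  transform when p < 0.05 (per variable × depth, logged); one-way ANOVA and
  Tukey HSD on the (possibly transformed) scale; means ± SE reported on the
  original scale.  The compact letter display uses the insert-and-absorb
  algorithm, which is transitive-consistent by construction.  All-zero
  within-group variance is reported as "no difference" (p = 1, shared
  letter) rather than an undefined F.
- **Correlations.**  Pairwise Pearson r with two-sided p, computed within
  each degraded+restored treatment pair; association with restoration is the
  point-biserial correlation against a 0/1 indicator inside that pair.
  Constant variables are omitted with a log entry.  No multiplicity
  correction beyond Tukey's family-wise control — correlation p-values are
  reported raw.
- **Random forest.**  1000 trees by default.  %IncMSE is computed by holdout
  permutation (30 % holdout, 10 permutations per predictor, all permuted
  copies scored in one batched predict); scikit-learn exposes no out-of-bag
  permutation importance, and with n = 18 an OOB scheme would rest on ~6
  samples per tree anyway.  The significance flag is an exact
  response-permutation test (the response is permuted and the entire
  fit-and-score procedure repeated, 99 times by default;
  p = (1+#{null ≥ observed})/(n_null+1)).  A t-test across the 10 holdout
  permutations was rejected: a forest partially fits noise predictors, so
  permuting them degrades prediction *genuinely* but trivially, and the
  t-test flags that real-but-meaningless effect.  The response-permutation
  null absorbs it.
- **Path analysis.**  Fully recursive system on z-scored variables; OLS per
  endogenous variable (the ML estimator for recursive models with
  uncorrelated errors), exogenous covariances fixed at their sample values,
  model-implied covariance Σ = (I−B)⁻¹Ψ(I−B)⁻ᵀ, and the ML discrepancy
  χ² = (n−1)(ln|Σ| − ln|S| + tr(SΣ⁻¹) − p) with
  df = p(p+1)/2 − (edges + error variances + exogenous moments).  χ²-p >
  0.05 is declared "consistent with data".  Standardized total effects are
  path-tracing sums of coefficient products, computed as (I−B)⁻¹ − I.  The
  outputs are labelled *path analysis*: no latent variables, no model
  search, no bootstrap intervals.  The default chain is
  angle → CUE_ST → POC → MAOC → SOC stock.

## The synthetic cohort generator

The generator emulates a cross-sectional survey a decade after restoration
of a severely desertified sandy alpine grassland: 3 treatments × 2 depths
(0–15, 15–30 cm) × 3 replicate plots.  Design decisions:

- **Distribution family.**  Each variable is log-normal, parameterised by
  (mean, CV), because all variables are positive and field soil data are
  right-skewed.  `cv = 0` is the exact noise-free degenerate (used by the
  identity tests).  Default CV is 0.15 for the effect-carrying variables —
  small enough that ANOVA at n = 3 resolves the large encoded effects —
  and tighter for bulk density (0.05), pH (0.03) and moisture (0.12), which
  vary little within a site.
- **Effect multipliers.**  Cell mean = degraded-topsoil baseline × depth
  attenuation × treatment multiplier.  Active-restoration multipliers encode
  the reported percent changes directly (e.g. AP ×27.89 topsoil / ×58.11
  subsoil; POC ×5.83/×7.21; MAOC ×6.57/×11.71); the reported SOC *stock*
  changes (+291 %/+467 %) are split between a SOC-concentration rise and a
  bulk-density decline.  Passive-restoration enzyme multipliers are not
  individually reported anywhere; modest values (C ×1.8–2.2, N ×1.5,
  AP ×1.0) were chosen so the passive cohort reproduces the reported
  qualitative pattern — vector angle up moderately, CUE_ST down ~10–20 %,
  C pools statistically unchanged at n = 3.
- **Enzyme baselines and the angle geometry.**  Because
  `tan(angle) = ln(Npool)/ln(AP)`, the angle rises under a multiplier set
  only if `ln(Npool)/ln(AP) < ln(N-mult)/ln(AP-mult)` at the baseline.  The
  reported multipliers raise AP far more than the N enzymes on the log
  scale, so baselines were chosen (urease-heavy N pool, AP ≈ 3.5 µmol-scale)
  to satisfy that inequality: the default cohort yields degraded angles of
  ≈ 22°/20° rising to ≈ 26°/23° under active restoration.  Absolute angle
  values are unit-dependent (see above) and are *not* generator targets;
  the ordering active > passive > degraded, with every sample N-limited, is.
- **POC/MAOC closure.**  The measured-pool total (POC+MAOC) is a fixed
  per-cell share `g` of each SOC draw, split by a Beta-distributed MAOC
  share (concentration 100; degenerate at its mean when the MAOC CV is 0).
  This guarantees POC + MAOC ≤ SOC row by row while keeping every
  configured mean exact in expectation.  Defaults put `g` in [0.91, 0.99]
  for every cell, so closure holds within 10 % of SOC everywhere.  Jointly
  honouring the reported fraction multipliers, the reported stock changes
  and closure forces the large active-restoration bulk-density decline
  (×0.66 topsoil, ×0.62 subsoil ≈ 1550 → 1020 kg m⁻³) — defensible for
  desertified sandy Arenosol recovering to meadow topsoil.
- **Seeding.**  One master seed; each (treatment × depth × variable) cell
  draws from its own deterministic child stream
  (`SeedSequence((seed, cell, variable))`), so a fixed seed reproduces the
  cohort bit for bit and adding replicates never reshuffles other cells.

**What the generator does not emulate:** temporal dynamics (only the
10-year endpoint cross-section), spatial autocorrelation between plots,
within-plot covariance beyond the POC/MAOC/SOC coupling (e.g. enzyme
activities are conditionally independent given the cell), assay measurement
error structure, and treatment × replicate interactions.  Passing the
end-to-end tests therefore shows that the *pipeline* recovers the encoded
contrasts under realistic skew and replication — not that the generator's
correlation structure matches real soils.

A further known consequence: with roughly stable biomass and resource C:N,
the encoded enzyme multipliers drive CUE_ST down by ~60 %/~90 % (top-/
subsoil, active) — larger than the ~54 %/34 % observed in the field, where
biomass stoichiometry co-varied with the enzymes.  No absolute CUE values
are available to calibrate against, so only the direction is treated as a
target.

## Numerical choices

- Percent changes: full precision internally; summaries round half away
  from zero to integer percent.
- Derived output tables at 6 significant digits; the cohort CSV at full
  float precision so `read(write(x)) == x` exactly.
- Limitation classification uses a sharp 45° threshold
  (`tolerance_deg = 0`); a tolerance band yielding a "balanced" class is
  available.
- Default pipeline seed 20220801 (the sampling campaign month; arbitrary
  but fixed).  All stochastic stages take explicit seeds.
- Check problem sizes: moment recovery at n = 1000 per cell (3 SE);
  ANOVA-vs-permutation agreement at 10⁵ permutations (|Δp| ≤ 0.01);
  vector-geometry oracle identity on 10⁴ random inputs; planted-signal
  forest recovery over 20 seeded replicates at n = 200 with 1000 trees;
  path-coefficient recovery at n = 1000 (±0.1); end-to-end direction
  pattern over 20 seeded cohorts (≥ 18 must pass).

## Known limitations

- Absolute vector angles and lengths are conditional on the activity unit
  convention; only contrasts are comparable across datasets.
- With 3 plots per cell, the per-depth path model (9 observations vs 9 free
  parameters) is unidentified; per-depth fits are reported only when n
  exceeds the parameter count, otherwise skipped with a message, and the
  pooled fit (n = 18) is the default.
- The pooled path chi-square typically *rejects* the simple chain on the
  default cohort: the generated data contain depth structure and direct
  angle–SOC association that the four-edge chain omits.  This is reported,
  not hidden.
- Random-forest importance on n = 18 with a 6-row holdout is noisy and its
  significance flags are rarely positive at that size; the stage is
  validated on larger planted-signal data.
- `EEA_N:P` is an interpreted formula (see above).
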