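# Methods

## The analysis pipeline

`aquahoney` replays an aquaphotomics analysis of heat-treated unifloral
honeys measured by near-infrared transflectance. The study design it
models: three honey types in different crystallization states (sunflower —
fully crystallized, bastard indigo — mid-crystallized, acacia — liquid),
each heated to 40/60/80/100 °C for 60/120/180/240 min plus an untreated
control (17 treatment levels), with three replicate bottles per level.
Each physical sample is scanned as 3 cuvette fills × 5 consecutive scans
(15 spectra per sample; 45 per level per honey; 765 per honey; 2295 total)
on a 900–1700 nm grid with a 3 nm step. All modelling uses the
1300–1600 nm first water overtone (101 wavelengths).

The stages, in replay order:

1. **Outlier screen** (per honey type, raw full-range spectra): PCA with
   rank chosen to reach 95 % explained variance (capped at 10), Hotelling
   T² on the retained scores with an F-distribution limit and Q residuals
   with Box's chi-square approximation, both at confidence 0.999. A
   spectrum is dropped when either statistic exceeds its limit.
2. **Range cut** to 1300–1600 nm, inclusive, bounds snapped to the grid.
3. **Pretreatment optimization** over a fixed grid of 41 pipelines
   (below), separately per modelling task.
4. **PCA-LDA classification** and **PLSR regression** with
   leave-one-replicate-out cross-validation.
5. **Subtraction spectra**, **wavelength voting** into the 12 water matrix
   coordinates (WAMACs), and **classic aquagrams** (8 per honey type, 24
   in total).
6. **HMF statistics**: assumption checks, one-/two-way ANOVA,
   Tukey/Games–Howell post hoc, star flags vs control, compact letter
   displays.

## Pretreatments and the 41-pipeline grid

Operators: Savitzky–Golay smoothing/differentiation (2nd-order polynomial;
windows 13/17/21; derivative order 0/1/2; derivatives in AU/nm^d, scaled
by the 3 nm step; edge handling by polynomial fit over the end windows),
SNV (per-spectrum standardization, population SD), MSC (per-spectrum
affine regression against the training-set mean; the corrected spectrum is
(y − intercept)/slope), and 2nd-order polynomial detrending. Pipelines are
encoded as strings (`sgol@2-21-0_snv` etc.); at most one scatter step
(SNV or MSC) per pipeline; steps apply in string order. MSC is the one
stateful step: its reference is fitted on the training fold only and
reused unchanged on held-out spectra.

The optimization grid is: `raw`; the four non-smoothed pipelines `snv`,
`msc`, `deTr`, `deTr_msc`; and, for each smoothing window w ∈ {13,17,21},
`sgol@2-w-0` alone, followed by one of {`snv`, `msc`, `deTr`, `deTr_snv`,
`deTr_msc`}, or followed by a derivative pass `sgol@2-w2-d` with
w2 ∈ {13,17,21}, d ∈ {1,2} — in total 1 + 4 + 3·(1 + 5 + 6) = 41
pipelines. The exact membership of the grid is a design choice: it is the
smallest natural product grid of the operators above that has exactly 41
members and contains every pipeline string our result tables print.

## Cross-validation

"Leave-one-sample-out" here means leave-one-replicate-out: each fold holds
out *all* fills and scans of one replicate bottle across every treatment
level (255 of 765 spectra per honey type). Any finer split would leak
scans of the same physical sample across the train/validation boundary.
Training and validation accuracies are fold-averaged; the control
correct-classification rate is computed from the pooled validation
confusion table.

## Models

**PCA** is mean-centred SVD with a deterministic sign convention (largest
|loading| element positive). **PCA-LDA** runs Gaussian LDA with a shared
within-class covariance on the first k PCA scores; the covariance gets a
ridge of 1e-8 × its trace (plus a 1e-12 absolute floor) so rank-deficient
folds stay invertible; priors are the training class proportions.
Discriminant directions are back-projected through the PCA loadings to
give per-wavelength weights. The rank k is chosen per task by maximizing
validation accuracy, tie-breaking by the smallest training−validation gap,
then the smallest k (candidates 2–15 by default; 3-fold CV with 51 samples
per type does not support more).

**PLSR** uses NIPALS (via scikit-learn, no column scaling); the number of
latent variables (1–12 by default) minimizes RMSECV over pooled
leave-one-replicate-out predictions. Reported metrics: R²C/RMSEC/RPDC from
the full-data fit, R²CV/RMSECV/RPDCV from the pooled CV predictions, with
RPD = SD(y)/RMSE (population SD) so that R² = 1 − 1/RPD² and a
mean-predictor scores RPD = 1, R² = 0 exactly. In temperature regressions
the control is coded 25 °C (room temperature; configurable, or excluded by
passing `control_temperature=None`); in time regressions it is 0 min.

## Wavelength voting and aquagrams

Each information source votes for its top-20 wavelengths: PCA display
models vote by |PC1 loading|, PCA-LDA models by the root-sum-square of the
back-projected discriminant weights, PLSR models by |regression vector|,
and subtraction spectra (group mean minus control mean, computed once on
MSC-corrected and once on Savitzky–Golay 2nd-derivative spectra) by their
local extrema. Votes are bucketed into the 12 WAMAC ranges (C1 1336–1348
… C12 1506–1520 nm; C12's upper bound is extended to 1520 nm so the
1511/1513 nm strongly-bonded-water anchors fall inside). Per WAMAC the
modal voted wavelength wins; ties break by summed vote magnitude, then
proximity to the range midpoint.

A classic aquagram takes one comparison set (e.g. control + the four
temperatures within one time interval), applies the display pretreatment
(Savitzky–Golay 2-21-0 smoothing + MSC against the comparison-set mean —
classic aquagrams need scatter-corrected, non-derivative absorbance), then
z-scores the absorbance at each selected coordinate over *all* spectra of
that comparison and averages per group. The size-weighted group mean is
therefore 0 at every coordinate, and the values are invariant to
duplicating spectra (population statistics). Normalizing per comparison
set (not over the whole study) matches the per-panel reading of the radar
charts.

## HMF statistics

Normality is checked per cell by Shapiro–Wilk (n ≥ 3 required) and
variance homogeneity by Levene (centred on the mean). Routing: Levene
p ≥ 0.05 → Tukey HSD, else Games–Howell, applied family-wise. Both tests
are implemented from summary statistics (mean, SD, n) — Tukey via the
pooled variance and the studentized range with df = N − k, Games–Howell
via per-pair Welch df — so the stage also runs on published mean ± SD
tables; the "±" is read as the sample SD of n = 3 replicates. The
module ships the study's published HMF summary for that mode. Star flags
vs the control require a significant one-way ANOVA over all 17 levels and
a post hoc p < 0.05 for the level-vs-control pair. Compact letter
displays use the insert-and-absorb algorithm, letters assigned in
ascending time/temperature order. Significance is fixed at 0.05; no
multiplicity correction beyond the post hoc methods themselves.

## The synthetic study generator

Real spectra of the original experiment are not publicly deposited, so the
package ships a generator that emulates the study's structure; every
pipeline stage is exercised end-to-end on its output.

Each noise-free spectrum is a shallow linear baseline plus Gaussian bands
at 1364, 1412, 1444, 1452, 1490, 1512 and 1583 nm (SDs 12–22 nm; the last
is the sugar band). Heat exposure enters through a scalar dose
d = (1 − 2^(−t/120 min)) · exp(0.04·(T − 40 °C)), zero for the control:
saturating in time, exponential in temperature, strictly monotone in both.
A fraction φ = 1 − exp(−0.25·d·crystallinity·sensitivity) of the
strongly hydrogen-bonded band mass (1490, 1512 nm) transfers to the free
water band (1412 nm), preserving total band mass — a see-saw that scatter
correction cannot remove, and the signature the aquagrams display. The
sugar band drifts up weakly (8 % at full dose).

Archetypes: sunflower (crystallinity 1.0), bastard indigo (0.55), acacia
(0.10, sensitivity 0.8). Noise layers: per-bottle multiplicative random
effects on the band weights (relative SD 4/5/12 % for
sunflower/bastard indigo/acacia) and on the dose response (30/40/60 % —
bottles crystallize differently, so a given dose remodels them unequally;
this is what keeps replicate-blocked validation below 100 % and makes
acacia models weak); per-fill multiplicative scatter (lognormal σ = 0.05)
and additive offset (SD 0.01 AU); per-scan white noise (SD 0.002 AU).
These levels were calibrated once so the sunflower detailed temperature
models land in the 85–100 % validation band with the control always
recognized, while acacia models are strictly weaker — the qualitative
ordering of the original results — and then frozen.

HMF values follow Arrhenius kinetics with an induction lag:
HMF = hmf₀·ε + rate(T)·t_eff·ε′, with rate(T) = 1.07·10⁻³ mg/kg/min ·
exp(16000 K·(1/313 K − 1/T)), t_eff = t⁴/(t³ + (120 min)³) and lognormal
noise ε (σ = 0.08). The lag makes short treatments at 80 °C
indistinguishable from control while 120 min and longer separate sharply,
as the published table shows; a lag-free linear-in-time model cannot
produce that pattern. Baselines hmf₀ are 18.5/14.7/7.0 mg/kg.

What the generator does *not* emulate: real crystallization/radiative-
transfer physics, instrument drift (the reference water scans exist in the
data model but carry no role), wavelength-correlated noise, and the exact
effect sizes of the original spectra (which are unavailable). Passing
tests therefore demonstrate that the pipeline recovers *planted* structure
under realistic noise of this form — not that it would reproduce the
original study's exact accuracy values on the original raw data.

## Numerical choices and degenerate inputs

- Range cut bounds snap to the nearest grid point; the synthetic grid is
  anchored at 901 nm so 1300 and 1600 nm are exact grid points (a
  900-anchored 3 nm grid contains neither).
- SNV raises on zero-variance rows; MSC raises on zero regression slope;
  aquagrams raise on zero-variance coordinates; PLSR raises on a constant
  target; folds require ≥ 2 replicate ids.
- Ties: pretreatment optimization keeps grid order; rank selection prefers
  smaller k; WAMAC vote ties prefer larger summed magnitude, then the
  range midpoint.
- All simulation randomness flows from one integer seed through
  `numpy.random.default_rng`; identical seeds give bit-identical spectra,
  HMF tables and metric CSVs.

## Problem sizes used by the shipped checks

The test suite and the acceptance script run the full 153-sample design
(2295 spectra). The acceptance script optimizes over the full 41-pipeline
grid; the test suite's full-replay checks use the 6-pipeline `fast` grid
(a structural property — model and aquagram counts — that does not depend
on grid membership), and the parameter-recovery tests run the full grid on
the tasks they assert about. The permuted-label null uses 20 permutations.

## Known limitations

- The published accuracy/R² values of the original study are not
  reproducible without its raw spectra; the package asserts structural and
  qualitative properties instead (model ordering across honey types,
  bound→free monotonicity, letter-display separations recomputed from the
  published HMF summary).
- Games–Howell with n = 3 replicates is fragile by nature (the per-pair
  variance estimate has 2 df); borderline star flags on synthetic HMF
  data are seed-sensitive, which is why those checks are seeded.
- The LDA uses a shared covariance with a fixed tiny ridge; no shrinkage
  estimation is attempted for very small folds.
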