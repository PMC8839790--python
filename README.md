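# aquahoney

Aquaphotomics analysis of heat treatment in unifloral honeys from
near-infrared (NIR) spectra.

Heating honey above 40 °C is restricted in many jurisdictions, but the
standard chemical marker — 5-hydroxymethylfurfural (HMF, legal limit
40 mg/kg) — only responds to severe treatments (≥ 80 °C for hours). The
water bands of the NIR first overtone (1300–1600 nm) are far more
sensitive: heat transfers absorbance from strongly hydrogen-bonded water
(~1489–1513 nm) to free-water conformations (~1405–1415 nm), and the size
of that shift depends on the honey's crystallization state. `aquahoney`
implements the full chemometric workflow that detects and visualizes this:

- **Spectra I/O** — wide-CSV reader/writer for absorbance tables with a
  treatment/replicate/fill/scan metadata hierarchy, wavelength-range
  cutting, and SIMCA-style outlier screening (Hotelling T² + Q residuals).
- **Pretreatment optimization** — Savitzky–Golay smoothing/derivatives,
  SNV, MSC, detrending; a canonical string codec (`sgol@2-21-0_snv`) and a
  41-combination optimization grid; MSC state is fitted on training folds
  only.
- **Modelling** — PCA, hybrid PCA-LDA classification and PLSR regression
  (R²/RMSE/RPD), all validated with leave-one-replicate-out
  cross-validation so no scan of a held-out bottle ever leaks into
  training, in statsmodels-style `Model.fit() → Results.summary()` form.
- **Aquagrams** — wavelength importance voting from model weights and
  subtraction spectra, bucketed into the 12 water matrix coordinates
  (WAMACs), classic aquagram computation and radar-chart rendering.
- **HMF statistics** — Shapiro–Wilk/Levene checks, one-/two-way ANOVA,
  Tukey or Games–Howell post hoc (computable from published mean ± SD
  summaries alone), star flags vs control, compact letter displays.
- **Synthetic study generator** — the original spectra are not publicly
  deposited, so the package ships a seeded generator that emulates the
  design (3 honey types × 17 heat levels × 3 bottles × 3 fills × 5 scans)
  and the bound→free water see-saw, letting every stage run end-to-end.

The scientific details and all default parameters are documented in
[`docs/methods.md`](docs/methods.md).

## Worked example

```python
from aquahoney import (
    DEFAULT_PARAMS, ModelTask, PCALDAModel, PLSRModel,
    cut_range, generate_design, generate_spectra, optimize_pretreatment,
)

params = DEFAULT_PARAMS.with_seed(1)
spectra = cut_range(generate_spectra(generate_design(), params), 1300, 1600)

task = ModelTask("detailed_temperature", "sunflower", 60)
best, report = optimize_pretreatment(spectra, task)   # scans all 41 pipelines
print(PCALDAModel(spectra, task, best).fit().summary())
```

```
                  PCA-LDA classification
==========================================================
Task:            sunflower: temperature within 60 min
Pretreatment:    snv
PCs:             2
Classes:         100, 40, 60, 80, CONTROL
CV scheme:       leave-one-replicate-out (3 folds)
----------------------------------------------------------
Training acc.:   100.00 %
Validation acc.: 100.00 %
Control acc.:    100.00 %
==========================================================
```

The temperature levels applied for 60 minutes to the (fully crystallized)
sunflower archetype are perfectly recognized on held-out bottles, and
every untreated control spectrum is classified as control — heat doses
this honey received are recoverable from its water spectral pattern alone.
Regression of the applied temperature works the same way:

```python
print(PLSRModel(spectra, ModelTask("general_temperature", "sunflower"),
                "sgol@2-21-0_snv").fit().summary())
```

```
                      PLS regression
==========================================================
Task:            sunflower: temperature (general)
Pretreatment:    sgol@2-21-0_snv
Latent vars:     3
----------------------------------------------------------
R2C  =  0.899   RMSEC  =    7.689 degC   RPDC  =  3.14
R2CV =  0.887   RMSECV =    8.125 degC   RPDCV =  2.97
==========================================================
```

An RPDCV near 3 means the cross-validated prediction error is about a
third of the spread of the applied temperatures — a usable calibration.
On the liquid acacia archetype the same models degrade sharply (R²CV can
drop below 0), reproducing the central observation that heat detection by
water spectral patterns is crystallization-dependent.

The full replay — outlier screen, range cut, pretreatment optimization for
every task, 24 detailed PCA-LDA + 24 detailed PLSR models, subtraction
spectra, WAMAC voting and 24 aquagrams, plus the HMF stage — runs from the
shell:

```bash
aquahoney run-study --seed 1 --out study_output      # full study replay
aquahoney simulate --seed 1 --out synthetic          # write synthetic CSVs
aquahoney model synthetic/spectra.csv --honey sunflower \
    --family detailed_temperature --group 60         # one task, 41 pipelines
aquahoney aquagram synthetic/spectra.csv --honey sunflower \
    --by temperature_C --group 60 --out radar.png
aquahoney hmf synthetic/hmf.csv --honey sunflower
```

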