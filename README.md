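# hepaquant

Combined morphological and functional liver-MRI biomarkers for detecting
liver cirrhosis, with a fully synthetic validation path.

Chronic liver disease progresses through fibrosis to cirrhosis, and
noninvasive staging matters because biopsy is risky and unsuited to
follow-up. Two MRI quantities track the two sides of that process:

- **T1ρ** (spin-lattice relaxation time in the rotating frame, ms) — the
  decay constant of transverse magnetisation during a spin-lock pulse,
  sensitive to macromolecular changes and therefore to fibrotic
  remodelling. It *increases* with fibrosis. Signal across spin-lock
  times T_SL follows S(T_SL) = S₀·exp(−T_SL/T1ρ), fitted per pixel by
  log-linear least squares: ln(S(T_SL)/S₀) = −T_SL/T1ρ + C.
- **RE** (relative enhancement, dimensionless) — hepatocyte uptake of the
  liver-specific contrast agent Gd-EOB-DTPA measured as
  RE = (SI_20min − SI_unenhanced)/SI_unenhanced on whole-liver ROIs in the
  hepatobiliary phase. It *decreases* as liver function declines.

Because the two move in opposite directions, their quotient — the
**fibrosis function quotient**, FFQ = T1ρ-cROI / RE (ms) — combines
morphology and function into a single marker that rises with liver
impairment.

The package provides, for whom this is built — imaging scientists
evaluating quantitative liver-MRI protocols:

- `hepaquant.relaxometry` — `T1RhoModel(series).fit()` → per-pixel T1ρ
  map with validity mask and fit diagnostics (statsmodels-style
  Model/Results pair);
- `hepaquant.roi` — the two reading protocols (mean of up to six 2–3 cm
  circular right-lobe ROIs, "T1ρ-cROI", vs one whole-liver ROI per slice,
  "T1ρ-wl"), vessel/tumor exclusion, edge-margin erosion, RE and FFQ;
- `hepaquant.phantom` / `hepaquant.cohort` — synthetic spin-lock phantoms
  and pre/post-contrast pairs with known ground truth, and subject
  cohorts drawn from per-group Gaussian biomarker distributions
  (defaults: 47 cirrhotic / 166 noncirrhotic subjects at the published
  group means/SDs);
- `hepaquant.diagnostics` — `DiagnosticsModel(cohort).fit()` → group
  t-tests, T1ρ–RE correlation, empirical ROC curves, AUC, Youden-index
  cutoffs, sensitivity/specificity and likelihood ratios;
- `hepaquant.pipeline` / a `hepaquant` CLI (`simulate`, `fit-t1rho`,
  `measure`, `evaluate`, `run-all`) with NIfTI/CSV/JSON I/O, seeds and
  provenance.

## Worked example

```python
import hepaquant as hq

# 1. phantom: known T1rho field, bright vessels, Gaussian noise
spec = hq.PhantomSpec(grid_shape=(128, 128), background_t1rho=50.0,
                      lesions=((40.0, 40.0, 10.0, 60.0),),
                      vessels=((80.0, 90.0, 3.0),), noise_sigma=10.0, seed=1)
phantom = hq.simulate_decay_series(spec)
fit = hq.T1RhoModel(phantom.series).fit()

# 2. cohort at the study's group parameters, diagnostic evaluation
cohort = hq.generate_cohort(hq.CohortSpec(seed=42))
print(hq.DiagnosticsModel(cohort).fit().summary())
```

The phantom map recovers the ground truth (parenchyma mean 50.02 ms vs
truth 50.00; lesion 59.98 ms vs 60.00 at noise σ=10), and the cohort
evaluation prints:

```
Diagnostic evaluation: cirrhosis vs no cirrhosis
subjects: 47 cirrhosis / 166 no cirrhosis

Group comparison (mean ± SD, Student's t-test)
  t1rho_croi_ms    51.37 ±  2.72  vs   47.58 ±  4.31   p = 3.89e-08
  t1rho_wl_ms      50.11 ±  3.28  vs   48.80 ±  4.31   p = 0.0546
  re                0.58 ±  0.08  vs    0.70 ±  0.13   p = 3.94e-08
  ffq_ms           89.61 ± 13.48  vs   71.01 ± 17.31   p = 1.05e-10

Pearson r (T1rho-cROI vs RE): -0.19 (p = 0.00526)

                 T1rho (cROI)  T1rho (wl)  Relative enhancement  Fibrosis function quotient
AUC                      0.77        0.59                  0.78                        0.83
Sensitivity (%)         91.49       95.74                 93.62                       97.87
...
```

Read: cirrhotic livers show higher T1ρ (51.4 vs 47.6 ms in circular
ROIs), lower enhancement (0.58 vs 0.70), and a clearly separated FFQ
(89.6 vs 71.0 ms); pooling both groups induces a negative T1ρ–RE
correlation; and the composite FFQ posts the best single-cohort AUC.
Single cohorts fluctuate — averages over many seeds are computed by the
reproduction script below.

## Command line

```sh
hepaquant run-all --outdir out/ --seed 1        # phantom → maps → cohort → report
hepaquant evaluate --subjects out/subjects.csv --out report.json --roc-out roc.csv
```

See `docs/methods.md` for the model details, generator assumptions and
known limitations.
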