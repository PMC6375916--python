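# Methods

## Relaxometry model

T1ρ-weighted signal under a spin-lock preparation of duration T_SL decays
mono-exponentially, S(T_SL) = S₀·exp(−T_SL/T1ρ). The production fit is
ordinary least squares in the log domain,

    ln(S(T_SL)/S₀) = −T_SL/T1ρ + C,    T1ρ = −1/slope,

with S₀ taken as the measured signal at the smallest *used* spin-lock
time. The default protocol uses all six acquired times
T_SL ∈ {0, 10, 20, 30, 40, 50} ms; any subset of at least five can be
selected (`use_tsl`), in which case the true S₀ is absorbed into the
intercept C and T1ρ is unaffected on noiseless data (subset-stability is
tested). The fit is unweighted — no variance reweighting of the
log-transformed samples — matching how clinical exponential-regression
plugins operate; a nonlinear signal-domain grid-search fit exists in the
test suite as an independent oracle only, because the log-domain OLS is
the method under study, not merely a numerical convenience.

Per-pixel rules: samples with non-positive signal are dropped
sample-wise (the log is undefined there); a pixel is **invalid** when
fewer than five usable samples remain, when the design is degenerate, or
when the fitted slope is ≥ 0 (no decay — e.g. flat bright vessel
signal). Invalid pixels carry NaN and are excluded by the validity mask,
never silently zero. R² is reported per pixel and clipped to [0, 1]
against floating-point fuzz. No spatial smoothing and no inter-frame
registration are applied.

## ROI protocols and biomarkers

Two aggregation protocols are implemented:

- **T1ρ-cROI**: up to three circular ROIs (default diameter 25 mm, i.e.
  the middle of the 2–3 cm protocol range) per slice on up to two
  slices, placed in vessel-free right-lobe parenchyma. The biomarker is
  the *unweighted mean of per-ROI means*: each ROI counts as one
  observation regardless of its pixel count. A pooled-pixel alternative
  is available by flag; the two coincide exactly for equal-sized ROIs
  and differ on gradients (both behaviours are tested).
- **T1ρ-wl**: one whole-liver ROI per slice, averaged across slices.

Both protocols respect an exclusion mask (vessels, tumor/ablation areas)
and an edge margin implemented as morphological erosion of the liver
mask by a physical distance (default 10 mm, converted through the pixel
spacing — default 300 mm FOV / 128 matrix ≈ 2.34 mm/px). Erosion is a
reproducible surrogate for the manual "stay ~1 cm from the liver edge"
rule. ROI *placement* is input, not computed: masks come from files or
from the phantom builder — automating placement on clinical images would
be a segmentation problem this package deliberately does not take on.

Relative enhancement uses whole-liver ROIs only:
RE = (SI_post − SI_pre)/SI_pre, where each SI term is the per-slice ROI
mean averaged across slices with equal slice weights (whether slices
should instead be area-weighted is unspecified in reading protocols;
equal weighting is the package's choice and is flagged here). The
fibrosis function quotient is FFQ = T1ρ-cROI / RE in ms, computed per
subject from that subject's own values. The distinction matters: a mean
of per-subject ratios is not the ratio of group means (51.11/0.59 ≈ 86.6
≠ the ~89.5 a cirrhotic group mean takes when each subject contributes
its own quotient), and the cohort generator reflects per-subject ratios.

## Synthetic data

**Phantoms** are circles on a uniform background: lesions override the
background T1ρ; vessels are flagged non-parenchyma and rendered as a
flat bright signal so that including them in an ROI measurably biases
the T1ρ estimate — this makes the circular-ROI vs whole-liver comparison
(vessel contamination degrades the whole-liver reading) demonstrable in
tests. Noise is additive Gaussian on the magnitude image by default;
at the SNR of liver imaging this keeps the log-linear fit effectively
unbiased and the Monte-Carlo checks tractable. Rician magnitude noise is
available as an option for low-SNR studies. The phantom makes no claim
to anatomical realism; it exists to validate the measurement chain
against known ground truth.

**Cohorts** draw per-group biomarkers from Gaussian distributions whose
default means/SDs are the study conditions (cirrhosis n=47:
T1ρ-cROI 51.11±3.45 ms, T1ρ-wl 50.44±3.16 ms, RE 0.59±0.11; no
cirrhosis n=166: 47.56±4.17, 49.14±4.21, 0.70±0.13; FFQ summaries
89.53±19.84 / 70.83±15.56 for the direct-draw mode). Within each group,
(T1ρ-cROI, RE) form a bivariate normal with configurable correlation;
the default is 0 because no within-group joint distribution is reported
anywhere — the pooled (both-groups) correlation then emerges purely from
the opposing separation of the group means, and the closed-form mixture
covariance gives r ≈ −0.117 at the default parameters (verified by brute
force in the tests). RE positivity is enforced by redrawing offending
(T1ρ-cROI, RE) pairs — truncation with redraw rather than clipping, so
the FFQ distribution acquires no atoms; at the default parameters the
truncated mass is ~1e−7 and the redraw loop is effectively never taken.
A bounded retry count turns pathological parameterisations into loud
errors. FFQ defaults to the per-subject ratio; `ffq_mode="gaussian"`
draws it directly from the per-group FFQ summaries instead, which is the
right emulation when FFQ's own published group statistics are the
quantity being reproduced (the ratio construction incidentally lands
within ~1% of those summaries by the delta method). The prior-intervention
flag is a label only (Bernoulli at the pooled observed rate 150/213,
identical in both groups for lack of a per-group breakdown).

What passing cohort tests show — and do not show: the generator
reproduces *group-level Gaussian summaries*, so simulation results
validate the statistical pipeline (ROC construction, cutoff selection,
test calibration) under those summaries. They do not certify behaviour
under real-world features the generator omits: non-Gaussian biomarker
distributions, reader variability in ROI placement, scanner and
sequence differences, or any dependence structure beyond the one
configured. Published *cutoffs* in particular transfer poorly: under the
Gaussian surrogate the optimal T1ρ-cROI cutoff sits near the binormal
crossing (~50.3 ms), not at the empirically published 48.34 ms, so
cutoffs are reported but never asserted against published values.

## Diagnostic evaluation

Positive class = cirrhosis. T1ρ-cROI, T1ρ-wl and FFQ are
higher-is-positive; RE is lower-is-positive and is ranked internally on
the negated score — order-equivalent to ranking on 1/RE for positive RE
(a monotone-invariance property the tests exercise) — while its cutoff
is reported on the original scale under the "positive if RE ≤ cutoff"
convention.

The empirical ROC uses every distinct observed value as a threshold;
the trapezoidal AUC then equals the Mann–Whitney pair-counting statistic
with ties counted ½, exactly, on every dataset (tested against a
brute-force pair count and against scikit-learn). Cutoffs maximise
Youden's J = sensitivity + specificity − 1; ties in J (compared with a
1e−12 tolerance, since TPR and FPR are ratios with different
denominators) resolve to the most sensitive threshold, a deterministic
convention chosen because screening use favours sensitivity. Likelihood
ratios are the algebraic identities PLR = sens/(1−spec),
NLR = (1−sens)/spec, with infinities flagged at the boundaries. Group
comparisons use the pooled-variance two-sided Student's t-test (Welch by
flag); correlation is Pearson's r with the t-transform p-value. No
multiple-testing correction and no AUC confidence intervals are applied
by default (a percentile bootstrap CI is available by flag). Predictive
values are deliberately absent: the study population's cirrhosis
prevalence is not representative, so PPV/NPV would mislead.

One documented inconsistency: in the published diagnostic-performance
table the RE column's PLR (1.84) does not satisfy PLR = sens/(1−spec)
for its own printed sensitivity/specificity (which give 1.74). The
package always reports the identity-consistent value; the discrepancy is
noted rather than reverse-engineered, since the intent behind the
printed number cannot be recovered.

## Reproduction study design

Cohort-level quantities are reproduced in expectation: 200 seeded
replicates of the full 47/166 cohort per quantity, which puts the Monte
Carlo standard error of a mean AUC near 0.003 — an order of magnitude
below the comparison bands — while keeping the whole script under a few
seconds on one CPU. With Gaussian group scores the expected empirical
AUC equals the binormal closed form Φ(Δμ/√(σ₁²+σ₀²)); the package
exposes that closed form as an independent oracle
(`study.binormal_reference_aucs`: 0.744 cROI, 0.598 wl, 0.741 RE, 0.771
FFQ at the default parameters).

## Numerical and design choices

- One global seed expands through `numpy.random.SeedSequence.spawn` into
  per-stage child streams, so any stage can be rerun in isolation while
  end-to-end runs stay bit-reproducible (the pipeline's subjects CSV is
  byte-identical across reruns of the same config).
- Degenerate inputs fail loudly with the offending name: empty effective
  ROIs name the ROI, missing CSV columns are listed, malformed CSV rows
  are reported with line numbers, pipeline stage failures name the stage.
  The one deliberate exception is per-pixel fitting, where degeneracy is
  data (an invalid pixel, not an exception).
- Biomarkers are carried at full precision; only presentation views
  round to two decimals.
- NIfTI label volumes for ROIs carry one label plane per slice (ROIs of
  different slices may overlap in-plane on a phantom re-using one grid).

## Known limitations

- No pulse-sequence physics: spin-lock preparation, B1/B0 inhomogeneity
  and motion artifacts are out of scope; artifact handling reduces to
  masking decisions.
- No automatic liver segmentation, vessel detection, or pre/post
  registration; DICOM ingestion is absent (the pipeline is NIfTI-native).
- The Gaussian cohort surrogate reproduces summary statistics, not the
  underlying patient distribution; see the cohort section for what that
  implies about transferable conclusions.
- Single-slice 2D geometry per acquisition; volumetric protocols would
  need an extended ROI model.
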