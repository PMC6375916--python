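"""Replicated synthetic-cohort studies of diagnostic performance.

Patient images behind the published group statistics are not public, so
cohort-level results are reproduced in expectation: cohorts are drawn
repeatedly from the configured per-group Gaussian biomarker distributions
and the empirical quantities (AUCs, pooled correlation, group means) are
averaged over replicates.  With Gaussian group scores the expected
empirical AUC equals the binormal closed form
``Phi(dmu / sqrt(sd1^2 + sd0^2))``, which serves as an independent check.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .cohort import CIRRHOSIS, CohortSpec, generate_cohort
from .diagnostics import BIOMARKERS, auc, pearson_r, roc_curve


def _replicate_rngs(seed: int, n_replicates: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n_replicates)]


def mean_auc_over_replicates(
    spec: CohortSpec,
    biomarkers: "list[str] | None" = None,
    n_replicates: int = 200,
    seed: int = 0,
) -> dict[str, float]:
    """Average empirical AUC per biomarker over seeded cohort replicates."""
    if biomarkers is None:
        biomarkers = list(BIOMARKERS)
    sums = dict.fromkeys(biomarkers, 0.0)
    for rng in _replicate_rngs(seed, n_replicates):
        cohort = generate_cohort(spec, rng=rng)
        labels = (cohort["group"] == CIRRHOSIS).to_numpy()
        for b in biomarkers:
            scores = cohort[b].to_numpy(float)
            sums[b] += auc(roc_curve(scores, labels, BIOMARKERS[b][1]))
    return {b: s / n_replicates for b, s in sums.items()}


def mean_pooled_correlation(
    spec: CohortSpec, x: str = "t1rho_croi_ms", y: str = "re",
    n_replicates: int = 200, seed: int = 0,
) -> float:
    """Average pooled (both groups combined) Pearson r over replicates."""
    total = 0.0
    for rng in _replicate_rngs(seed, n_replicates):
        total += pearson_r(generate_cohort(spec, rng=rng), x, y)[0]
    return total / n_replicates


def mean_group_mean(
    spec: CohortSpec, group: str = CIRRHOSIS, biomarker: str = "t1rho_croi_ms",
    n_replicates: int = 200, seed: int = 0,
) -> float:
    """Grand mean of per-replicate group sample means (generator calibration)."""
    total = 0.0
    for rng in _replicate_rngs(seed, n_replicates):
        cohort = generate_cohort(spec, rng=rng)
        total += float(cohort.loc[cohort["group"] == group, biomarker].mean())
    return total / n_replicates


def binormal_auc(mean_pos: float, sd_pos: float, mean_neg: float, sd_neg: float) -> float:
    """Closed-form AUC of two Gaussian score distributions (positive class
    oriented so that larger scores indicate disease)."""
    return float(norm.cdf((mean_pos - mean_neg) / np.hypot(sd_pos, sd_neg)))


def binormal_reference_aucs(spec: CohortSpec | None = None) -> dict[str, float]:
    """Binormal AUCs implied by the configured group parameters, oriented
    per biomarker (RE is lower-is-positive)."""
    spec = spec or CohortSpec(seed=0)
    p1 = spec.group_params[CIRRHOSIS]
    p0 = spec.group_params["none"]
    out = {}
    for column, key in [
        ("t1rho_croi_ms", "t1rho_croi"),
        ("t1rho_wl_ms", "t1rho_wl"),
        ("re", "re"),
        ("ffq_ms", "ffq"),
    ]:
        (m1, s1), (m0, s0) = p1[key], p0[key]
        if BIOMARKERS[column][1] == "lower_is_positive":
            m1, m0 = -m1, -m0
        out[column] = binormal_auc(m1, s1, m0, s0)
    return out
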