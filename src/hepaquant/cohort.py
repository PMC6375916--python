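"""Synthetic patient cohorts with the study's group-level biomarker structure.

Each subject carries four biomarkers — T1rho-cROI (ms), T1rho-wl (ms),
relative enhancement RE (dimensionless) and the fibrosis function quotient
FFQ (ms) — plus a cirrhosis label and a prior-intervention flag.  Within
each diagnostic group, (T1rho-cROI, RE) are drawn from a bivariate normal
with a configurable within-group correlation (default 0: any pooled
correlation across the full cohort then arises purely from the separation
of the group means), and T1rho-wl from an independent normal.

FFQ is, by default, computed per subject as that subject's own
``t1rho_croi / re`` — a mean of ratios, which is not the ratio of the group
means.  ``ffq_mode="gaussian"`` instead draws FFQ directly from per-group
normal distributions (requires an ``"ffq"`` entry in ``group_params``),
useful when FFQ summary statistics are the quantity being emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CIRRHOSIS = "cirrhosis"
NO_CIRRHOSIS = "none"

#: Published group means/SDs for the three measured biomarkers
#: (cirrhosis n=47 vs no cirrhosis n=166).
STUDY_GROUP_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    CIRRHOSIS: {
        "t1rho_croi": (51.11, 3.45),
        "t1rho_wl": (50.44, 3.16),
        "re": (0.59, 0.11),
        "ffq": (89.53, 19.84),
    },
    NO_CIRRHOSIS: {
        "t1rho_croi": (47.56, 4.17),
        "t1rho_wl": (49.14, 4.21),
        "re": (0.70, 0.13),
        "ffq": (70.83, 15.56),
    },
}

#: Pooled prior-intervention rate in the study population (150 of 213);
#: a per-group breakdown is not available, so both groups share it.
STUDY_INTERVENTION_FRACTION = 150.0 / 213.0

SUBJECT_COLUMNS = [
    "subject_id",
    "group",
    "prior_intervention",
    "t1rho_croi_ms",
    "t1rho_wl_ms",
    "re",
    "ffq_ms",
]


def _default_group_params() -> dict[str, dict[str, tuple[float, float]]]:
    return {g: dict(v) for g, v in STUDY_GROUP_PARAMS.items()}


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a synthetic cohort; defaults are the study conditions."""

    n_cirrhosis: int = 47
    n_noncirrhosis: int = 166
    group_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=_default_group_params
    )
    within_group_corr: float = 0.0
    intervention_fraction: float = STUDY_INTERVENTION_FRACTION
    ffq_mode: str = "ratio"  # or "gaussian"
    seed: int = 0
    max_redraw_rounds: int = 100

    def __post_init__(self) -> None:
        if self.n_cirrhosis < 0 or self.n_noncirrhosis < 0:
            raise ValueError("group sizes must be >= 0")
        if not -1.0 <= self.within_group_corr <= 1.0:
            raise ValueError("within_group_corr must lie in [-1, 1]")
        if not 0.0 <= self.intervention_fraction <= 1.0:
            raise ValueError("intervention_fraction must lie in [0, 1]")
        if self.ffq_mode not in ("ratio", "gaussian"):
            raise ValueError(f"unknown ffq_mode {self.ffq_mode!r}")
        for grp in (CIRRHOSIS, NO_CIRRHOSIS):
            if grp not in self.group_params:
                raise ValueError(f"group_params missing group {grp!r}")
            params = self.group_params[grp]
            needed = {"t1rho_croi", "t1rho_wl", "re"}
            if self.ffq_mode == "gaussian":
                needed.add("ffq")
            missing = needed - set(params)
            if missing:
                raise ValueError(f"group {grp!r} missing biomarker params {sorted(missing)}")
            for name, (_, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"{grp}/{name}: sd must be >= 0")


def _draw_group(
    spec: CohortSpec, group: str, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    p = spec.group_params[group]
    (m_croi, s_croi), (m_wl, s_wl), (m_re, s_re) = p["t1rho_croi"], p["t1rho_wl"], p["re"]
    rho = spec.within_group_corr

    # (croi, re) via a Cholesky-style transform of iid normals so that
    # positivity redraws replace whole pairs without disturbing the joint law
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    croi = m_croi + s_croi * z1
    re = m_re + s_re * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)
    for _ in range(spec.max_redraw_rounds):
        bad = re <= 0
        if not bad.any():
            break
        k = int(bad.sum())
        z1b = rng.standard_normal(k)
        z2b = rng.standard_normal(k)
        croi[bad] = m_croi + s_croi * z1b
        re[bad] = m_re + s_re * (rho * z1b + np.sqrt(1.0 - rho**2) * z2b)
    else:
        raise RuntimeError(
            f"could not draw strictly positive RE for group {group!r} within "
            f"{spec.max_redraw_rounds} redraw rounds (params {p['re']})"
        )
    wl = m_wl + s_wl * rng.standard_normal(n)

    if spec.ffq_mode == "gaussian":
        m_ffq, s_ffq = p["ffq"]
        ffq = m_ffq + s_ffq * rng.standard_normal(n)
        for _ in range(spec.max_redraw_rounds):
            bad = ffq <= 0
            if not bad.any():
                break
            ffq[bad] = m_ffq + s_ffq * rng.standard_normal(int(bad.sum()))
        else:
            raise RuntimeError(f"could not draw positive FFQ for group {group!r}")
    else:
        ffq = croi / re

    intervention = rng.random(n) < spec.intervention_fraction
    return pd.DataFrame(
        {
            "group": group,
            "prior_intervention": intervention.astype(int),
            "t1rho_croi_ms": croi,
            "t1rho_wl_ms": wl,
            "re": re,
            "ffq_ms": ffq,
        }
    )


def generate_cohort(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw one synthetic cohort as a subjects table.

    Columns: ``subject_id, group, prior_intervention, t1rho_croi_ms,
    t1rho_wl_ms, re, ffq_ms``.  Bit-reproducible for a fixed spec (the seed
    lives in the spec); pass an explicit ``rng`` to drive replicates from an
    external seed stream.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    parts = []
    if spec.n_cirrhosis:
        parts.append(_draw_group(spec, CIRRHOSIS, spec.n_cirrhosis, rng))
    if spec.n_noncirrhosis:
        parts.append(_draw_group(spec, NO_CIRRHOSIS, spec.n_noncirrhosis, rng))
    if parts:
        df = pd.concat(parts, ignore_index=True)
    else:
        df = pd.DataFrame({c: pd.Series(dtype=float) for c in SUBJECT_COLUMNS[1:]})
        df["group"] = df.get("group", pd.Series(dtype=str))
    df.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(df))])
    return df[SUBJECT_COLUMNS]
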