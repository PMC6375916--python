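"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library code paths they check:
the nonlinear relaxometry fit searches a T1rho grid in signal space, the
AUC oracle counts positive/negative pairs, and the Youden oracle sweeps
every candidate threshold explicitly.
"""

from __future__ import annotations

import numpy as np
import pytest

import hepaquant as hq


@pytest.fixture()
def rng():
    return np.random.default_rng(20190214)


@pytest.fixture()
def uniform_phantom():
    """Noiseless 32x32 phantom, T1rho = 50 ms everywhere, no vessels."""
    return hq.PhantomSpec(grid_shape=(32, 32), background_t1rho=50.0, s0_value=1000.0)


@pytest.fixture()
def vessel_phantom():
    """48x48 phantom with a 60 ms lesion and two bright vessels."""
    return hq.PhantomSpec(
        grid_shape=(48, 48),
        background_t1rho=48.0,
        lesions=((12.0, 12.0, 5.0, 60.0),),
        vessels=((30.0, 30.0, 3.0), (10.0, 36.0, 2.0)),
        s0_value=1000.0,
    )


@pytest.fixture()
def default_cohort():
    return hq.generate_cohort(hq.CohortSpec(seed=7))


# ---------------------------------------------------------------- oracles


def gridsearch_t1rho(signals, tsl, t1_grid=None):
    """Signal-space nonlinear fit: for each candidate T1rho the optimal
    amplitude is S0 = sum(S*e)/sum(e*e); minimise the residual sum of
    squares over a dense grid."""
    signals = np.asarray(signals, float)
    tsl = np.asarray(tsl, float)
    if t1_grid is None:
        t1_grid = np.linspace(1.0, 200.0, 20000)
    best = (np.inf, np.nan)
    for t1 in t1_grid:
        e = np.exp(-tsl / t1)
        s0 = float(signals @ e) / float(e @ e)
        ss = float(((signals - s0 * e) ** 2).sum())
        if ss < best[0]:
            best = (ss, t1)
    return best[1]


def pair_count_auc(scores, labels):
    """Mann-Whitney AUC: fraction of (positive, negative) pairs ranked
    correctly, ties counted one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def exhaustive_youden(scores, labels, orientation):
    """Best (J, sens, spec, cutoff) by sweeping every observed value as a
    cutoff under the 'positive if >= c' (or '<= c') rule; ties resolve to
    the most sensitive cutoff."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    best = None
    candidates = np.unique(scores)
    if orientation == hq.diagnostics.HIGHER:
        order = candidates  # ascending: later candidates are LESS sensitive
        sens_spec = lambda c: ((pos >= c).mean(), (neg < c).mean())
        prefer_smaller = True
    else:
        order = candidates[::-1]
        sens_spec = lambda c: ((pos <= c).mean(), (neg > c).mean())
        prefer_smaller = False
    for c in order:
        sens, spec = sens_spec(c)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, sens, spec, c)
        elif abs(j - best[0]) <= 1e-12:
            # tie: keep the more sensitive (smaller for higher-is-positive,
            # larger for lower-is-positive) cutoff
            if (c < best[3]) == prefer_smaller and c != best[3]:
                best = (j, sens, spec, c)
    return best


def mixture_pearson_r(spec: hq.CohortSpec, x: str = "t1rho_croi", y: str = "re") -> float:
    """Closed-form pooled correlation of two biomarkers across the
    two-group Gaussian mixture (within-group correlation from the spec)."""
    n1, n0 = spec.n_cirrhosis, spec.n_noncirrhosis
    p = n1 / (n1 + n0)
    (mx1, sx1), (mx0, sx0) = spec.group_params["cirrhosis"][x], spec.group_params["none"][x]
    (my1, sy1), (my0, sy0) = spec.group_params["cirrhosis"][y], spec.group_params["none"][y]
    rho = spec.within_group_corr if {x, y} == {"t1rho_croi", "re"} else 0.0
    dx, dy = mx1 - mx0, my1 - my0
    cov = p * rho * sx1 * sy1 + (1 - p) * rho * sx0 * sy0 + p * (1 - p) * dx * dy
    vx = p * sx1**2 + (1 - p) * sx0**2 + p * (1 - p) * dx**2
    vy = p * sy1**2 + (1 - p) * sy0**2 + p * (1 - p) * dy**2
    return cov / np.sqrt(vx * vy)
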