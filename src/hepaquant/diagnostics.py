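"""Diagnostic evaluation: group comparisons, correlation, ROC analysis.

The positive class throughout is *cirrhosis*.  T1rho-cROI, T1rho-wl and
FFQ increase with cirrhosis (``higher_is_positive``); relative enhancement
decreases (``lower_is_positive``).  Lower-is-positive markers are ranked
internally on the negated score — for strictly positive RE this is
order-equivalent to ranking on 1/RE — while cutoffs are reported on the
original scale with the convention "positive if score <= cutoff".

The empirical ROC curve uses every distinct observed value as a
threshold; its trapezoidal area equals the Mann–Whitney pair-counting
statistic (ties counted 1/2) exactly.  Cutoffs maximise Youden's
J = sensitivity + specificity − 1, with ties broken toward the more
sensitive threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CIRRHOSIS, NO_CIRRHOSIS

HIGHER = "higher_is_positive"
LOWER = "lower_is_positive"

#: Biomarker column -> (display label, orientation)
BIOMARKERS: dict[str, tuple[str, str]] = {
    "t1rho_croi_ms": ("T1rho (cROI)", HIGHER),
    "t1rho_wl_ms": ("T1rho (wl)", HIGHER),
    "re": ("Relative enhancement", LOWER),
    "ffq_ms": ("Fibrosis function quotient", HIGHER),
}


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve from (0,0) to (1,1).

    ``thresholds`` are on the original biomarker scale, one per curve vertex
    (the (0,0) vertex carries an infinite threshold).  A point's (fpr, tpr)
    is the operating characteristic of the rule "positive if score >=
    threshold" (``higher_is_positive``) or "<= threshold" (``lower_is_positive``).
    """

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    orientation: str
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class DiagnosticReport:
    biomarker: str
    label: str
    orientation: str
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    plr: float
    nlr: float
    n_positive: int
    n_negative: int


@dataclass(frozen=True)
class GroupComparison:
    biomarker: str
    mean_positive: float
    sd_positive: float
    n_positive: int
    mean_negative: float
    sd_negative: float
    n_negative: int
    t_statistic: float
    p_value: float
    welch: bool


def _scores_labels(cohort: pd.DataFrame, biomarker: str) -> tuple[np.ndarray, np.ndarray]:
    if biomarker not in cohort.columns:
        raise KeyError(f"cohort table has no biomarker column {biomarker!r}")
    scores = cohort[biomarker].to_numpy(dtype=float)
    labels = (cohort["group"] == CIRRHOSIS).to_numpy()
    if not np.all(np.isfinite(scores)):
        raise ValueError(f"non-finite values in biomarker {biomarker!r}")
    return scores, labels


def roc_curve(scores, labels, orientation: str = HIGHER) -> RocCurve:
    """Empirical ROC of ``scores`` against boolean ``labels`` (True = positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    if orientation not in (HIGHER, LOWER):
        raise ValueError(f"unknown orientation {orientation!r}")

    s = scores if orientation == HIGHER else -scores
    # thresholds descending on the internal scale: "positive if s >= t"
    uniq = np.unique(s)[::-1]
    pos_sorted = np.sort(s[labels])
    neg_sorted = np.sort(s[~labels])
    # P(s >= t) per class via right-side search on the sorted samples
    tp = n_pos - np.searchsorted(pos_sorted, uniq, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, uniq, side="left")
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thr_internal = np.concatenate([[np.inf], uniq])
    thresholds = thr_internal if orientation == HIGHER else -thr_internal
    return RocCurve(
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
        orientation=orientation,
        n_positive=n_pos,
        n_negative=n_neg,
    )


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the empirical ROC curve."""
    return float(np.trapezoid(curve.tpr, curve.fpr))


def youden_cutoff(curve: RocCurve) -> tuple[float, float, float]:
    """Cutoff maximising Youden's J; returns (cutoff, sensitivity, specificity).

    Ties in J are broken toward the most sensitive operating point, i.e. the
    smallest cutoff for higher-is-positive markers and the largest for
    lower-is-positive ones.
    """
    j = curve.tpr - curve.fpr
    # later vertices have smaller internal thresholds (more sensitive rules),
    # so a tie in J resolves to the last maximiser; ties are compared with a
    # tolerance because tpr/fpr are ratios with different denominators
    idx = int(np.flatnonzero(j >= j.max() - 1e-12)[-1])
    return float(curve.thresholds[idx]), float(curve.tpr[idx]), float(1.0 - curve.fpr[idx])


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[float, float]:
    """PLR = sens/(1−spec), NLR = (1−sens)/spec; boundary cases give inf/nan."""
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if specificity == 1.0:
        plr = math.inf if sensitivity > 0 else math.nan
    else:
        plr = sensitivity / (1.0 - specificity)
    if specificity == 0.0:
        nlr = math.inf if sensitivity < 1 else math.nan
    else:
        nlr = (1.0 - sensitivity) / specificity
    return plr, nlr


def compare_groups(
    cohort: pd.DataFrame, biomarker: str, welch: bool = False
) -> GroupComparison:
    """Two-sided t-test of a biomarker between cirrhotic and noncirrhotic groups.

    Pooled-variance Student's t by default, Welch by flag; SDs use the n−1
    denominator.
    """
    scores, labels = _scores_labels(cohort, biomarker)
    pos, neg = scores[labels], scores[~labels]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"t-test needs >=2 subjects per group (got {len(pos)} / {len(neg)})"
        )
    t, p = stats.ttest_ind(pos, neg, equal_var=not welch)
    return GroupComparison(
        biomarker=biomarker,
        mean_positive=float(pos.mean()),
        sd_positive=float(pos.std(ddof=1)),
        n_positive=len(pos),
        mean_negative=float(neg.mean()),
        sd_negative=float(neg.std(ddof=1)),
        n_negative=len(neg),
        t_statistic=float(t),
        p_value=float(p),
        welch=welch,
    )


def pearson_r(cohort: pd.DataFrame, x: str, y: str) -> tuple[float, float]:
    """Pearson correlation between two biomarker columns, pooled over groups."""
    xs, _ = _scores_labels(cohort, x)
    ys, _ = _scores_labels(cohort, y)
    if len(xs) < 3:
        raise ValueError("Pearson correlation needs >=3 paired values")
    if np.std(xs) == 0 or np.std(ys) == 0:
        raise ValueError("Pearson correlation undefined for zero-variance input")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def evaluate_biomarker(
    cohort: pd.DataFrame, biomarker: str, orientation: str | None = None, label: str | None = None
) -> DiagnosticReport:
    if orientation is None:
        if biomarker not in BIOMARKERS:
            raise KeyError(
                f"no default orientation for {biomarker!r}; pass orientation explicitly"
            )
        label_default, orientation = BIOMARKERS[biomarker]
        label = label or label_default
    scores, labels = _scores_labels(cohort, biomarker)
    curve = roc_curve(scores, labels, orientation)
    if min(curve.n_positive, curve.n_negative) < 2:
        warnings.warn(
            f"{biomarker}: fewer than 2 subjects in a class; estimates are unstable",
            stacklevel=2,
        )
    cutoff, sens, spec = youden_cutoff(curve)
    plr, nlr = likelihood_ratios(sens, spec)
    return DiagnosticReport(
        biomarker=biomarker,
        label=label or biomarker,
        orientation=orientation,
        auc=auc(curve),
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        plr=plr,
        nlr=nlr,
        n_positive=curve.n_positive,
        n_negative=curve.n_negative,
    )


def evaluate_biomarkers(cohort: pd.DataFrame, biomarkers=None) -> list[DiagnosticReport]:
    """One diagnostic report per biomarker, at each marker's own orientation."""
    if biomarkers is None:
        biomarkers = list(BIOMARKERS)
    missing = [b for b in biomarkers if b not in cohort.columns]
    if missing:
        raise KeyError(f"cohort table is missing biomarker column(s) {missing}")
    return [evaluate_biomarker(cohort, b) for b in biomarkers]


def bootstrap_auc_ci(
    scores, labels, orientation: str = HIGHER, n_boot: int = 1000,
    alpha: float = 0.05, seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC (stratified resampling)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    rng = np.random.default_rng(seed)
    pos, neg = scores[labels], scores[~labels]
    vals = np.empty(n_boot)
    for i in range(n_boot):
        bs = np.concatenate([rng.choice(pos, pos.size), rng.choice(neg, neg.size)])
        bl = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
        vals[i] = auc(roc_curve(bs, bl, orientation))
    lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


class DiagnosticsModel:
    """Cohort-level diagnostic evaluation model.

    Built from a subjects table (one row per subject with the four
    biomarker columns plus ``group``); ``fit()`` computes group
    comparisons, the T1rho–RE correlation, ROC curves and per-biomarker
    diagnostic reports, returned as a :class:`DiagnosticsResults`.
    """

    def __init__(self, cohort: pd.DataFrame, biomarkers=None, welch: bool = False):
        if "group" not in cohort.columns:
            raise KeyError("cohort table needs a 'group' column")
        bad = set(cohort["group"]) - {CIRRHOSIS, NO_CIRRHOSIS}
        if bad:
            raise ValueError(f"unknown group labels {sorted(bad)}")
        self.cohort = cohort
        self.biomarkers = list(biomarkers) if biomarkers is not None else list(BIOMARKERS)
        self.welch = welch

    @classmethod
    def from_csv(cls, path, **kwargs) -> "DiagnosticsModel":
        from .io import read_subjects

        return cls(read_subjects(path), **kwargs)

    def fit(self) -> "DiagnosticsResults":
        reports = evaluate_biomarkers(self.cohort, self.biomarkers)
        comparisons = [
            compare_groups(self.cohort, b, welch=self.welch) for b in self.biomarkers
        ]
        curves = {}
        for b in self.biomarkers:
            scores, labels = _scores_labels(self.cohort, b)
            curves[b] = roc_curve(scores, labels, BIOMARKERS.get(b, ("", HIGHER))[1])
        corr = corr_p = float("nan")
        if {"t1rho_croi_ms", "re"} <= set(self.cohort.columns):
            corr, corr_p = pearson_r(self.cohort, "t1rho_croi_ms", "re")
        return DiagnosticsResults(
            model=self,
            reports=reports,
            comparisons=comparisons,
            roc_curves=curves,
            t1rho_re_r=corr,
            t1rho_re_p=corr_p,
        )


@dataclass(frozen=True)
class DiagnosticsResults:
    """Fitted diagnostic evaluation: reports, tests, curves, summary table."""

    model: DiagnosticsModel = field(repr=False)
    reports: list[DiagnosticReport]
    comparisons: list[GroupComparison]
    roc_curves: dict[str, RocCurve] = field(repr=False)
    t1rho_re_r: float
    t1rho_re_p: float

    def report_frame(self) -> pd.DataFrame:
        """Diagnostic-performance table: rows = statistics, columns = biomarkers."""
        cols = {}
        for rep in self.reports:
            cols[rep.label] = {
                "AUC": rep.auc,
                "Cutoff": rep.cutoff,
                "Sensitivity (%)": 100.0 * rep.sensitivity,
                "Specificity (%)": 100.0 * rep.specificity,
                "PLR": rep.plr,
                "NLR": rep.nlr,
            }
        return pd.DataFrame(cols)

    def comparison_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.comparisons:
            rows.append(
                {
                    "biomarker": c.biomarker,
                    "cirrhosis_mean": c.mean_positive,
                    "cirrhosis_sd": c.sd_positive,
                    "noncirrhosis_mean": c.mean_negative,
                    "noncirrhosis_sd": c.sd_negative,
                    "t": c.t_statistic,
                    "p_value": c.p_value,
                }
            )
        return pd.DataFrame(rows).set_index("biomarker")

    def summary(self) -> str:
        """Human-readable summary in the style of a diagnostic-performance table."""
        n_pos = self.reports[0].n_positive if self.reports else 0
        n_neg = self.reports[0].n_negative if self.reports else 0
        out = [
            "Diagnostic evaluation: cirrhosis vs no cirrhosis",
            f"subjects: {n_pos} cirrhosis / {n_neg} no cirrhosis",
            "",
            "Group comparison (mean ± SD, Student's t-test"
            + (" [Welch]" if self.model.welch else "")
            + ")",
        ]
        for c in self.comparisons:
            out.append(
                f"  {c.biomarker:<14} {c.mean_positive:7.2f} ± {c.sd_positive:5.2f}"
                f"  vs {c.mean_negative:7.2f} ± {c.sd_negative:5.2f}"
                f"   p = {c.p_value:.3g}"
            )
        if np.isfinite(self.t1rho_re_r):
            out.append("")
            out.append(
                f"Pearson r (T1rho-cROI vs RE): {self.t1rho_re_r:+.2f}"
                f" (p = {self.t1rho_re_p:.3g})"
            )
        out.append("")
        frame = self.report_frame().round(2)
        out.append(frame.to_string())
        return "\n".join(out)

    def plot_roc(self, ax=None):
        """Plot all ROC curves on one axis (lower-is-positive markers are
        plotted from their internally flipped curve, matching a 1/RE view)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for rep in self.reports:
            curve = self.roc_curves[rep.biomarker]
            ax.plot(curve.fpr, curve.tpr, label=f"{rep.label} (AUC={rep.auc:.2f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("Sensitivity")
        ax.legend(loc="lower right", fontsize=8)
        return ax
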