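"""ROC analysis, cutoffs, likelihood ratios, group statistics."""

import numpy as np
import pandas as pd
import pytest

import hepaquant as hq
from hepaquant.diagnostics import HIGHER, LOWER
from conftest import exhaustive_youden, pair_count_auc


def _cohort_from_scores(pos, neg, column="t1rho_croi_ms"):
    df = pd.DataFrame(
        {
            "group": [hq.CIRRHOSIS] * len(pos) + [hq.NO_CIRRHOSIS] * len(neg),
            column: list(pos) + list(neg),
        }
    )
    return df


def _random_scores(rng, n_pos=None, n_neg=None, ties=True):
    n_pos = n_pos or rng.integers(2, 12)
    n_neg = n_neg or rng.integers(2, 12)
    if ties:
        pool = rng.integers(0, 8, n_pos + n_neg).astype(float)
    else:
        pool = rng.normal(size=n_pos + n_neg)
    labels = np.array([True] * n_pos + [False] * n_neg)
    return pool, labels


class TestRocCurve:
    def test_perfect_separation(self):
        curve = hq.roc_curve([2.0, 3.0, 0.0, 1.0], [True, True, False, False], HIGHER)
        assert hq.auc(curve) == 1.0
        # the curve passes through (fpr=0, tpr=1)
        assert any(f == 0.0 and t == 1.0 for f, t in zip(curve.fpr, curve.tpr))

    def test_endpoints_and_monotonicity(self, rng):
        scores, labels = _random_scores(rng)
        curve = hq.roc_curve(scores, labels)
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()

    def test_orientation_flip_mirrors_auc(self, rng):
        for _ in range(25):
            scores, labels = _random_scores(rng)
            a_hi = hq.auc(hq.roc_curve(scores, labels, HIGHER))
            a_lo = hq.auc(hq.roc_curve(scores, labels, LOWER))
            assert a_lo == pytest.approx(1.0 - a_hi, abs=1e-12)

    def test_negation_equals_reciprocal_for_positive_scores(self, rng):
        """For strictly positive scores, ranking on -x and on 1/x coincide:
        the lower-is-positive AUC equals the higher-is-positive AUC of the
        reciprocal (monotone invariance)."""
        scores = rng.uniform(0.1, 2.0, 30)
        labels = rng.random(30) < 0.4
        if labels.all() or not labels.any():
            labels[:2] = [True, False]
        a_lower = hq.auc(hq.roc_curve(scores, labels, LOWER))
        a_recip = hq.auc(hq.roc_curve(1.0 / scores, labels, HIGHER))
        assert a_lower == pytest.approx(a_recip, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores, labels = _random_scores(rng, ties=False)
        a = hq.auc(hq.roc_curve(scores, labels))
        b = hq.auc(hq.roc_curve(np.exp(scores), labels))
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            hq.roc_curve([1.0, 2.0], [True, True])


class TestAuc:
    def test_all_ties_gives_half(self):
        curve = hq.roc_curve([5.0] * 6, [True, True, False, False, False, False])
        assert hq.auc(curve) == pytest.approx(0.5)

    def test_trapezoid_equals_pair_counting_on_random_cohorts(self):
        """Exact equality of the trapezoidal area and the Mann-Whitney
        pair statistic (ties counted 1/2) on 100 random small cohorts."""
        rng = np.random.default_rng(99)
        for _ in range(100):
            scores, labels = _random_scores(rng)
            a = hq.auc(hq.roc_curve(scores, labels))
            assert a == pytest.approx(pair_count_auc(scores, labels), abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            scores, labels = _random_scores(rng)
            a = hq.auc(hq.roc_curve(scores, labels))
            assert a == pytest.approx(sklearn_metrics.roc_auc_score(labels, scores), abs=1e-12)


class TestYoudenCutoff:
    def test_perfect_separation_returns_positive_boundary(self):
        curve = hq.roc_curve([2.0, 3.0, 0.0, 1.0], [True, True, False, False])
        cutoff, sens, spec = hq.youden_cutoff(curve)
        assert (sens, spec) == (1.0, 1.0)
        assert cutoff == 2.0  # smallest threshold achieving J = 1

    def test_all_equal_scores_degenerate(self):
        curve = hq.roc_curve([5.0] * 5, [True, False, False, True, False])
        cutoff, sens, spec = hq.youden_cutoff(curve)
        assert sens + spec - 1.0 == pytest.approx(0.0)
        assert cutoff == 5.0

    @pytest.mark.parametrize("orientation", [HIGHER, LOWER])
    def test_matches_exhaustive_search(self, orientation):
        rng = np.random.default_rng(7)
        for _ in range(100):
            scores, labels = _random_scores(rng)
            curve = hq.roc_curve(scores, labels, orientation)
            cutoff, sens, spec = hq.youden_cutoff(curve)
            j_o, sens_o, spec_o, cut_o = exhaustive_youden(scores, labels, orientation)
            assert sens + spec - 1.0 == pytest.approx(j_o, abs=1e-12)
            assert cutoff == pytest.approx(cut_o)
            assert (sens, spec) == pytest.approx((sens_o, spec_o))

    def test_lower_is_positive_cutoff_on_original_scale(self):
        """An RE-like marker keeps its cutoff on the original scale with the
        'positive if score <= cutoff' convention."""
        pos = [0.5, 0.55, 0.6]
        neg = [0.7, 0.75, 0.8]
        curve = hq.roc_curve(pos + neg, [True] * 3 + [False] * 3, LOWER)
        cutoff, sens, spec = hq.youden_cutoff(curve)
        assert cutoff == pytest.approx(0.6)
        assert (sens, spec) == (1.0, 1.0)


class TestLikelihoodRatios:
    @pytest.mark.parametrize(
        "sens,spec,plr,nlr",
        [
            (0.702, 0.765, 2.99, 0.39),  # FFQ-scale operating point
            (0.830, 0.602, 2.09, 0.28),  # cROI-scale operating point
            (1.0, 1.0, np.inf, 0.0),
        ],
    )
    def test_identities(self, sens, spec, plr, nlr):
        got_plr, got_nlr = hq.likelihood_ratios(sens, spec)
        if np.isinf(plr):
            assert np.isinf(got_plr)
        else:
            assert round(got_plr, 2) == plr
        assert round(got_nlr, 2) == nlr

    def test_boundary_flags(self):
        plr, nlr = hq.likelihood_ratios(0.5, 0.0)
        assert np.isinf(nlr) and plr == 0.5
        with pytest.raises(ValueError):
            hq.likelihood_ratios(1.2, 0.5)


class TestGroupStats:
    def test_identical_groups_p_one(self):
        df = _cohort_from_scores([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        cmp = hq.compare_groups(df, "t1rho_croi_ms")
        assert cmp.p_value == pytest.approx(1.0)
        assert cmp.mean_positive == cmp.mean_negative

    def test_strong_separation_tiny_p(self):
        df = _cohort_from_scores([10.0, 10.1, 10.2, 9.9], [1.0, 1.1, 0.9, 1.05])
        cmp = hq.compare_groups(df, "t1rho_croi_ms")
        assert cmp.p_value < 1e-6
        assert cmp.mean_positive > cmp.mean_negative

    def test_welch_flag_changes_statistic(self):
        rng = np.random.default_rng(0)
        df = _cohort_from_scores(rng.normal(1, 3, 10), rng.normal(0, 0.3, 40))
        pooled = hq.compare_groups(df, "t1rho_croi_ms", welch=False)
        welch = hq.compare_groups(df, "t1rho_croi_ms", welch=True)
        assert pooled.p_value != welch.p_value

    def test_degenerate_group_rejected(self):
        df = _cohort_from_scores([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            hq.compare_groups(df, "t1rho_croi_ms")

    def test_t_test_power_at_study_conditions(self):
        """At the configured group separation for T1rho-cROI (n=47/166) the
        pooled t-test rejects at alpha=0.001 in nearly every replicate."""
        spec = hq.CohortSpec(seed=0)
        reject = 0
        seeds = np.random.SeedSequence(77).spawn(200)
        for ss in seeds:
            df = hq.generate_cohort(spec, rng=np.random.default_rng(ss))
            if hq.compare_groups(df, "t1rho_croi_ms").p_value < 0.001:
                reject += 1
        assert reject / 200 > 0.95

    def test_pearson_trivial_and_errors(self):
        df = pd.DataFrame({"group": ["cirrhosis"] * 4, "a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        r, _ = hq.pearson_r(df, "a", "b")
        assert r == pytest.approx(1.0)
        df["c"] = -df["a"]
        assert hq.pearson_r(df, "a", "c")[0] == pytest.approx(-1.0)
        df["d"] = 5.0
        with pytest.raises(ValueError, match="zero-variance"):
            hq.pearson_r(df, "a", "d")


class TestEvaluateBiomarkers:
    def test_perfectly_separated_cohort_all_auc_one(self):
        n1, n0 = 5, 7
        df = pd.DataFrame(
            {
                "group": [hq.CIRRHOSIS] * n1 + [hq.NO_CIRRHOSIS] * n0,
                "t1rho_croi_ms": [60.0] * n1 + [40.0] * n0,
                "t1rho_wl_ms": [58.0] * n1 + [42.0] * n0,
                "re": [0.4] * n1 + [0.9] * n0,  # lower in cirrhosis
                "ffq_ms": [150.0] * n1 + [44.0] * n0,
            }
        )
        reports = hq.evaluate_biomarkers(df)
        assert [r.auc for r in reports] == [1.0] * 4

    def test_orientations_assigned_per_biomarker(self, default_cohort):
        reports = {r.biomarker: r for r in hq.evaluate_biomarkers(default_cohort)}
        assert reports["re"].orientation == LOWER
        assert reports["t1rho_croi_ms"].orientation == HIGHER
        # all AUCs comfortably above chance under the study conditions
        assert all(r.auc > 0.5 for r in reports.values())

    def test_single_subject_per_class_warns(self):
        df = pd.DataFrame(
            {
                "group": [hq.CIRRHOSIS, hq.NO_CIRRHOSIS],
                "t1rho_croi_ms": [55.0, 45.0],
            }
        )
        with pytest.warns(UserWarning, match="fewer than 2"):
            rep = hq.diagnostics.evaluate_biomarker(df, "t1rho_croi_ms")
        assert rep.auc == 1.0

    def test_missing_column_named(self, default_cohort):
        df = default_cohort.drop(columns=["ffq_ms"])
        with pytest.raises(KeyError, match="ffq_ms"):
            hq.evaluate_biomarkers(df)


class TestDiagnosticsModel:
    def test_fit_results_consistent_with_operations(self, default_cohort):
        res = hq.DiagnosticsModel(default_cohort).fit()
        assert len(res.reports) == 4
        for rep in res.reports:
            plr, nlr = hq.likelihood_ratios(rep.sensitivity, rep.specificity)
            assert rep.plr == pytest.approx(plr)
            assert rep.nlr == pytest.approx(nlr)
        frame = res.report_frame()
        assert frame.shape == (6, 4)
        assert "AUC" in frame.index
        assert "T1rho (cROI)" in res.summary()

    def test_unknown_group_label_rejected(self, default_cohort):
        bad = default_cohort.copy()
        bad.loc[0, "group"] = "maybe"
        with pytest.raises(ValueError, match="maybe"):
            hq.DiagnosticsModel(bad)

    def test_bootstrap_ci_brackets_auc(self, default_cohort):
        scores = default_cohort["ffq_ms"].to_numpy()
        labels = (default_cohort["group"] == hq.CIRRHOSIS).to_numpy()
        a = hq.auc(hq.roc_curve(scores, labels))
        lo, hi = hq.diagnostics.bootstrap_auc_ci(scores, labels, n_boot=200, seed=1)
        assert lo < a < hi
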