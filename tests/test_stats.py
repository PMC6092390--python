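"""Cohort statistics: filtering, adjusted trends, ROC/Youden diagnostics."""

import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import delong_brute_force, mann_whitney_auc, youden_exhaustive
from octaquant import (
    CohortSpec,
    auc_with_ci,
    diagnostic_table,
    filter_quality,
    fit_adjusted_trend,
    generate_cohort,
    roc_points,
    youden_cutoff,
)


class TestFilterQuality:
    def test_all_above_threshold_unchanged(self, reference_cohort):
        df = reference_cohort.copy()
        df["ssi"] = 70.0
        assert len(filter_quality(df)) == len(df)

    def test_boundary_is_strict(self, reference_cohort):
        df = reference_cohort.copy()
        df["ssi"] = 70.0
        df.loc[df.index[:5], "ssi"] = 60.0  # exactly at the threshold: removed
        kept = filter_quality(df)
        assert len(kept) == len(df) - 5

    def test_mixed_counts_match_direct_count(self, reference_cohort):
        kept = filter_quality(reference_cohort)
        assert len(kept) == int((reference_cohort["ssi"] > 60).sum())

    def test_idempotent(self, reference_cohort):
        once = filter_quality(reference_cohort)
        twice = filter_quality(once)
        assert once.equals(twice)


class TestAdjustedTrend:
    @staticmethod
    def slope_cohort(slope, seed, n_per=83, sd=3.0, tau=1.5, bilateral=0.6):
        means = {"cvi": tuple(69.21 + slope * g for g in range(6))}
        return generate_cohort(CohortSpec(
            group_sizes=(n_per,) * 6,
            group_metric_means=means,
            group_metric_sds={"cvi": (sd,) * 6},
            patient_effect_sd=tau,
            fraction_bilateral=bilateral,
            seed=seed,
        ))

    def test_recovers_generating_slope(self):
        hits = 0
        for seed in range(10):
            tr = fit_adjusted_trend(self.slope_cohort(-0.68, seed), "cvi")
            hits += abs(tr.beta - (-0.68)) <= 2 * tr.se
        assert hits >= 8

    def test_null_slope_covered(self):
        hits = 0
        for seed in range(10):
            tr = fit_adjusted_trend(self.slope_cohort(0.0, 50 + seed), "cvi")
            hits += abs(tr.beta) <= 2 * tr.se
        assert hits >= 8

    def test_singleton_patients_match_ols(self):
        # with one eye per patient the GLS weights are uniform, so the
        # mixed-model slope equals OLS regardless of the variance split
        import statsmodels.formula.api as smf

        cohort = self.slope_cohort(-0.68, 3, tau=0.0, bilateral=0.0)
        tr = fit_adjusted_trend(cohort, "cvi")
        df = cohort.rename(columns={"cvi": "y"}).assign(severity=lambda d: d["group"].astype(float))
        ols = smf.ols("y ~ severity + age + sex + dbp", df).fit()
        assert tr.beta == pytest.approx(ols.params["severity"], abs=1e-6)

    def test_needs_two_groups(self, reference_cohort):
        single = reference_cohort[reference_cohort["group"] == 1]
        with pytest.raises(ValueError):
            fit_adjusted_trend(single, "cvi")


class TestROC:
    def test_perfect_separation(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        curve = roc_points(scores, labels)
        assert curve.auc == 1.0
        assert any((f == 0.0 and t == 1.0) for f, t in zip(curve.fpr, curve.tpr))

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=4000)
        labels = rng.integers(0, 2, size=4000)
        assert roc_points(scores, labels).auc == pytest.approx(0.5, abs=0.03)

    def test_curve_monotone_and_anchored(self):
        rng = np.random.default_rng(1)
        scores = rng.integers(0, 8, size=60).astype(float)  # heavy ties
        labels = rng.integers(0, 2, size=60)
        c = roc_points(scores, labels)
        assert c.fpr[0] == 0.0 and c.tpr[0] == 0.0
        assert c.fpr[-1] == 1.0 and c.tpr[-1] == 1.0
        assert (np.diff(c.fpr) >= 0).all() and (np.diff(c.tpr) >= 0).all()

    def test_trapezoid_equals_mann_whitney(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(6, 25))
            scores = rng.integers(0, 6, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            c = roc_points(scores, labels, auto_orient=False)
            expected = mann_whitney_auc(scores, labels)
            assert c.auc == pytest.approx(expected, abs=1e-12)

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(size=200)
        labels = (rng.random(200) < 1 / (1 + np.exp(-scores))).astype(int)
        a1 = roc_points(scores, labels).auc
        a2 = roc_points(np.exp(scores) + 5 * scores**3, labels).auc
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_points(np.arange(5.0), np.ones(5, int))

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(4)
        scores = rng.normal(size=300)
        labels = (scores + rng.normal(size=300) > 0).astype(int)
        assert roc_points(scores, labels).auc == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


class TestAUCConfidence:
    def test_perfect_separation_ci(self):
        scores = np.r_[np.zeros(10), np.ones(10)]
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        auc, (lo, hi) = auc_with_ci(scores, labels)
        assert auc == 1.0 and hi == 1.0

    def test_delong_matches_brute_force(self):
        rng = np.random.default_rng(5)
        from octaquant.stats import _delong_variance

        for _ in range(30):
            n = int(rng.integers(8, 21))
            scores = np.round(rng.normal(size=n), 1)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() < 2 or labels.sum() > n - 2:
                continue
            auc_f, var_f = _delong_variance(scores, labels)
            auc_b, var_b = delong_brute_force(scores, labels)
            assert auc_f == pytest.approx(auc_b, abs=1e-12)
            assert var_f == pytest.approx(var_b, abs=1e-12)

    def test_binormal_limit(self):
        from scipy.stats import norm

        delta = np.sqrt(2) * norm.ppf(0.9)  # analytic AUC = 0.9
        rng = np.random.default_rng(6)
        scores = np.r_[rng.normal(0, 1, 2000), rng.normal(delta, 1, 2000)]
        labels = np.r_[np.zeros(2000, int), np.ones(2000, int)]
        auc, _ = auc_with_ci(scores, labels)
        assert auc == pytest.approx(0.9, abs=0.03)

    def test_bootstrap_option(self):
        rng = np.random.default_rng(7)
        scores = np.r_[rng.normal(0, 1, 60), rng.normal(1, 1, 60)]
        labels = np.r_[np.zeros(60, int), np.ones(60, int)]
        auc, (lo, hi) = auc_with_ci(scores, labels, method="bootstrap",
                                    n_boot=300, seed=0)
        assert lo <= auc <= hi


class TestYouden:
    def test_clean_gap_midpoint(self):
        scores = np.r_[np.full(8, 0.2), np.full(8, 0.8)]
        labels = np.r_[np.ones(8, int), np.zeros(8, int)]  # diseased low
        res = youden_cutoff(scores, labels)
        assert res.j == 1.0
        assert res.cutoff == pytest.approx(0.5)
        assert res.lower_indicates_disease

    def test_matches_exhaustive_search(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            n = int(rng.integers(6, 30))
            scores = rng.integers(0, 10, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                continue
            res = youden_cutoff(scores, labels)
            assert res.j == pytest.approx(youden_exhaustive(scores, labels), abs=1e-12)

    def test_single_overlap_contingency(self):
        # diseased: 1, 2, 3; healthy: 3, 4, 5 -> cutoff 3.5, classify < 3.5
        scores = np.array([1.0, 2.0, 3.0, 3.0, 4.0, 5.0])
        labels = np.array([1, 1, 1, 0, 0, 0])
        res = youden_cutoff(scores, labels)
        assert res.cutoff == pytest.approx(3.5)
        assert res.sensitivity == pytest.approx(1.0)      # 3/3 diseased below
        assert res.specificity == pytest.approx(2 / 3)    # 2/3 healthy above
        assert res.sens_ci[0] < res.sensitivity <= res.sens_ci[1]

    def test_constant_scores_warn(self):
        scores = np.ones(10)
        labels = np.r_[np.zeros(5, int), np.ones(5, int)]
        with pytest.warns(UserWarning):
            res = youden_cutoff(scores, labels)
        assert res.j == 0.0


class TestDiagnosticTable:
    def test_contrast_class_sizes(self, reference_cohort):
        d1 = diagnostic_table(reference_cohort, "faz_circ_scp", "no_dr_vs_dr")
        assert (d1.n_negative, d1.n_positive) == (30, 102)
        d2 = diagnostic_table(reference_cohort, "faz_circ_scp", "early_vs_advanced")
        assert (d2.n_negative, d2.n_positive) == (75, 57)

    def test_circularity_beats_vessel_density(self, reference_cohort):
        # at the deep plexus the standardized group separation of the
        # circularity index (~1.1 SD) dwarfs that of vessel density
        # (~0.2 SD), so its AUC should dominate
        d_circ = diagnostic_table(reference_cohort, "faz_circ_dcp", "no_dr_vs_dr")
        d_vd = diagnostic_table(reference_cohort, "vd_dcp", "no_dr_vs_dr")
        assert d_circ.auc > d_vd.auc

    def test_orientation_flags(self, reference_cohort):
        lower_markers = diagnostic_table(reference_cohort, "cvi", "no_dr_vs_dr")
        higher_markers = diagnostic_table(reference_cohort, "faz_perim_scp", "no_dr_vs_dr")
        assert lower_markers.lower_indicates_disease
        assert not higher_markers.lower_indicates_disease

    def test_constant_metric_warns_auc_half(self, reference_cohort):
        df = reference_cohort.copy()
        df["flat"] = 1.0
        with pytest.warns(UserWarning):
            d = diagnostic_table(df, "flat", "no_dr_vs_dr")
        assert d.auc == 0.5

    def test_unknown_contrast_rejected(self, reference_cohort):
        with pytest.raises(ValueError):
            diagnostic_table(reference_cohort, "cvi", "sick_vs_well")

    def test_healthy_controls_optional_in_negatives(self, reference_cohort):
        base = diagnostic_table(reference_cohort, "cvi", "no_dr_vs_dr")
        with_ctrl = diagnostic_table(reference_cohort, "cvi", "no_dr_vs_dr",
                                     include_healthy=True)
        assert with_ctrl.n_negative == base.n_negative + 42


def test_schema_validation_names_missing_column(reference_cohort):
    df = reference_cohort.drop(columns=["patient_id"])
    with pytest.raises(ValueError, match="patient_id"):
        filter_quality(df)
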