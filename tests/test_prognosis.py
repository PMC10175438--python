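"""Prognostic classification, ROC/Youden cut-off, KM, log-rank and Cox."""

import numpy as np
import pandas as pd
import pytest

from gaparea3d import (
    REFERENCE_CUTOFF_TABLE,
    build_cutoff_table,
    classify_prognosis,
    cox_fit,
    high_risk_flag,
    km_estimate,
    logrank_test,
    reduction_adequacy,
    roc_curve,
    select_cutoff,
    youden_j,
)


class TestClassification:
    @pytest.mark.parametrize(
        "area,group",
        [
            (0.0, "excellent"),
            (141.0, "excellent"),  # the worked clinical example
            (150.0, "excellent"),
            (150.1, "good"),
            (550.0, "good"),
            (550.1, "moderate"),
            (1000.0, "moderate"),
            (1000.1, "poor"),
            (1200.0, "poor"),
        ],
    )
    def test_half_open_boundaries(self, area, group):
        assert classify_prognosis(area) == group

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            classify_prognosis(-1.0)

    @pytest.mark.parametrize(
        "area,flag", [(550.0, True), (549.9, False), (954.5, True), (0.0, False)]
    )
    def test_high_risk_flag(self, area, flag):
        assert high_risk_flag(area) is flag

    def test_flag_and_group_agree_except_exactly_at_cutoff(self):
        for area in (100.0, 400.0, 549.9, 550.1, 800.0, 1500.0):
            assert high_risk_flag(area) == (classify_prognosis(area) in ("moderate", "poor"))
        # the published convention is inconsistent exactly at 550
        assert high_risk_flag(550.0) and classify_prognosis(550.0) == "good"


class TestYoudenAndCutoff:
    def test_published_operating_points_are_internally_consistent(self):
        """J recomputed from each printed (sens, spec) pair matches the
        printed J to two decimals for all five cut-offs."""
        for row in REFERENCE_CUTOFF_TABLE.itertuples():
            j = youden_j(row.sensitivity_pct / 100, row.specificity_pct / 100)
            # half of the printed precision, with float slack: the 950 mm^2
            # row sits exactly on the rounding boundary (J = 0.355)
            assert j == pytest.approx(row.youden_j, abs=0.005 + 1e-9)

    @pytest.mark.parametrize(
        "sens,spec,j", [(1.0, 1.0, 1.0), (0.5, 0.5, 0.0), (0.915, 0.414, 0.329)]
    )
    def test_youden_values(self, sens, spec, j):
        assert youden_j(sens, spec) == pytest.approx(j, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            youden_j(1.2, 0.5)

    def test_reference_table_selects_550(self):
        assert select_cutoff(REFERENCE_CUTOFF_TABLE) == 550.0

    def test_single_candidate(self):
        assert select_cutoff(pd.DataFrame({"cutoff_mm2": [300.0], "youden_j": [0.2]})) == 300.0

    def test_tie_breaks_to_smaller_cutoff(self):
        table = pd.DataFrame({"cutoff_mm2": [700.0, 400.0], "youden_j": [0.4, 0.4]})
        assert select_cutoff(table) == 400.0

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            select_cutoff(pd.DataFrame({"cutoff_mm2": [], "youden_j": []}))

    def test_cutoff_table_monotonicity(self, rng):
        scores = rng.lognormal(6, 1, 300)
        labels = rng.random(300) < 1 / (1 + np.exp(-(np.log(scores) - 6)))
        if labels.all() or not labels.any():
            pytest.skip("degenerate draw")
        table = build_cutoff_table(scores, labels)
        sens = table.sort_values("cutoff_mm2")["sensitivity_pct"].to_numpy()
        spec = table.sort_values("cutoff_mm2")["specificity_pct"].to_numpy()
        assert (np.diff(sens) <= 1e-9).all()
        assert (np.diff(spec) >= -1e-9).all()


class TestROC:
    def test_perfect_separation(self):
        r = roc_curve([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert r.auc == pytest.approx(1.0)

    def test_auc_equals_pairwise_rank_statistic(self, rng):
        """AUC must equal the Mann-Whitney pair count, brute-forced."""
        scores = rng.normal(size=60)
        labels = rng.random(60) < 0.4
        if labels.all() or not labels.any():
            pytest.skip("degenerate draw")
        r = roc_curve(scores, labels)
        pos = scores[labels]
        neg = scores[~labels]
        wins = sum(
            1.0 if p > q else 0.5 if p == q else 0.0 for p in pos for q in neg
        )
        assert r.auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_chance_level_on_independent_labels(self, rng):
        scores = rng.normal(size=10_000)
        labels = rng.random(10_000) < 0.5
        assert roc_curve(scores, labels).auc == pytest.approx(0.5, abs=0.02)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1.0, 2.0], [1, 1])


class TestKaplanMeier:
    def test_no_censoring_matches_empirical_survival(self):
        curve = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        assert curve.survival_at(2.5) == pytest.approx(0.5)
        for t in (0.5, 1.5, 2.5, 3.5, 4.5):
            ecdf = np.mean(np.array([1.0, 2.0, 3.0, 4.0]) <= t)
            assert curve.survival_at(t) == pytest.approx(1 - ecdf)

    def test_hand_computed_product_limit_with_censoring(self):
        # times {1, 2+, 3, 4}: S(3) = (3/4) * (1/2) = 0.375
        curve = km_estimate([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 1])
        assert curve.survival_at(3.0) == pytest.approx(0.375)

    def test_all_censored_is_flat_one(self):
        curve = km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(curve.survival == 1.0)

    def test_survival_is_monotone_in_unit_interval(self, rng):
        t = rng.exponential(5, 200) + 1e-6
        e = rng.random(200) < 0.7
        curve = km_estimate(t, e)
        assert curve.survival[0] <= 1.0 + 1e-12
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert (curve.survival >= 0).all()

    def test_grouped_estimate(self):
        curves = km_estimate([1, 2, 3, 4.0], [1, 1, 1, 1], ["a", "a", "b", "b"])
        assert set(curves) == {"a", "b"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


def _logrank_by_hand(groups):
    """Observed-minus-expected tabulation at each distinct event time."""
    all_times = sorted(
        {t for times, events, in groups for t, e in zip(times, events) if e}
    )
    o_minus_e = np.zeros(len(groups))
    var = np.zeros(len(groups))
    for t in all_times:
        at_risk = np.array([np.sum(np.asarray(ts) >= t) for ts, _ in groups])
        deaths = np.array(
            [
                np.sum((np.asarray(ts) == t) & np.asarray(es, bool))
                for ts, es in groups
            ]
        )
        n, d = at_risk.sum(), deaths.sum()
        expected = d * at_risk / n
        o_minus_e += deaths - expected
        if n > 1:
            var += d * (at_risk / n) * (1 - at_risk / n) * (n - d) / (n - 1)
    return o_minus_e, var


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        g = ([1.0, 2.0, 3.0, 5.0], [1, 0, 1, 1])
        res = logrank_test([g, g])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.df == 1

    def test_matches_hand_tabulation_on_small_example(self):
        g1 = ([1.0, 3.0, 5.0, 7.0], [1, 1, 0, 1])
        g2 = ([2.0, 4.0, 6.0, 8.0], [1, 0, 1, 1])
        res = logrank_test([g1, g2])
        o_minus_e, var = _logrank_by_hand([g1, g2])
        expected_chi2 = o_minus_e[0] ** 2 / var[0]
        assert res.statistic == pytest.approx(expected_chi2, rel=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([([1.0], [1]), ([], [])])

    def test_type_one_error_is_calibrated(self, rng):
        """Null rejection rate at alpha=0.05 across simulated replicates."""
        rejections = 0
        reps = 300
        for _ in range(reps):
            t1 = rng.exponential(5, 40)
            t2 = rng.exponential(5, 40)
            res = logrank_test([(t1, np.ones(40)), (t2, np.ones(40))])
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / reps <= 0.08


class TestCox:
    def _simulate(self, rng, n=1000, beta=np.log(2)):
        x = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1.0 / np.exp(beta * x))
        c = rng.uniform(0.2, 3.0, n)
        return pd.DataFrame(
            {
                "followup_years": np.minimum(t, c) + 1e-9,
                "tka": (t <= c).astype(int),
                "x": x,
            }
        )

    def test_recovers_true_log_hazard_ratio(self, rng):
        df = self._simulate(rng)
        fit = cox_fit(df, ["x"])
        assert fit.n_events >= 300
        assert fit.coef[0] == pytest.approx(np.log(2), abs=0.2)
        assert fit.ci_lower[0] < fit.hazard_ratios[0] < fit.ci_upper[0]

    def test_null_covariate_is_covered(self, rng):
        """|log-HR| < 2 SE in at least 90% of null replicates."""
        hits = 0
        reps = 60
        for _ in range(reps):
            df = self._simulate(rng, n=400, beta=0.0)
            fit = cox_fit(df, ["x"])
            hits += abs(fit.coef[0]) < 2 * fit.se[0]
        assert hits / reps >= 0.90

    def test_matches_lifelines_on_continuous_times(self, rng):
        from lifelines import CoxPHFitter

        df = self._simulate(rng, n=300)
        fit = cox_fit(df, ["x"])  # Breslow; no ties so Efron coincides
        cph = CoxPHFitter().fit(df, "followup_years", "tka")
        assert fit.coef[0] == pytest.approx(cph.params_["x"], abs=1e-5)
        assert fit.se[0] == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_sign_matches_early_event_group(self, rng):
        # group with systematically earlier events must get positive log-HR
        t0 = rng.exponential(3.0, 100)
        t1 = rng.exponential(0.5, 100)
        df = pd.DataFrame(
            {
                "followup_years": np.concatenate([t0, t1]) + 1e-9,
                "tka": np.ones(200, int),
                "x": np.concatenate([np.zeros(100), np.ones(100)]),
            }
        )
        assert cox_fit(df, ["x"]).coef[0] > 0

    def test_constant_covariate_rejected(self):
        df = pd.DataFrame(
            {"followup_years": [1.0, 2.0, 3.0], "tka": [1, 0, 1], "x": [1.0, 1.0, 1.0]}
        )
        with pytest.raises(ValueError, match="no variation"):
            cox_fit(df, ["x"])

    def test_no_events_rejected(self):
        df = pd.DataFrame(
            {"followup_years": [1.0, 2.0], "tka": [0, 0], "x": [0.0, 1.0]}
        )
        with pytest.raises(ValueError):
            cox_fit(df, ["x"])


class TestReductionAdequacy:
    @pytest.mark.parametrize(
        "gap,step,ok",
        [(2.0, 2.0, True), (2.1, 0.0, False), (0.0, 0.0, True), (0.0, 2.5, False)],
    )
    def test_two_millimetre_rule_is_inclusive(self, gap, step, ok):
        assert reduction_adequacy(gap, step) is ok

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            reduction_adequacy(-0.1, 0.0)
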