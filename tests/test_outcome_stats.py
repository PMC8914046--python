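"""Endpoint logic, survival statistics, NNT and image-quality scoring."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from rvstrain.errors import SchemaError, StatsError
from rvstrain.stats import (
    auc,
    composite_endpoint,
    cox_fit,
    dichotomize,
    endpoint_table,
    image_quality_score,
    km_estimate,
    logrank_test,
    nested_lrt,
    nnt_binary,
    nnt_continuous,
)
from rvstrain.synthetic import generate_cohort
from rvstrain.tree import _logrank_chi2


class TestCompositeEndpoint:
    def test_hierarchy_label_with_first_event_time(self):
        rec = composite_endpoint(
            [("hf_hospitalization", 10.0), ("cardiac_death", 14.0)], 24.0, "s1"
        )
        assert (rec.label, rec.time_months, rec.status) == ("cardiac_death", 10.0, 1)

    def test_no_event_censors_at_followup_end(self):
        rec = composite_endpoint([], 24.0)
        assert (rec.status, rec.time_months, rec.label) == (0, 24.0, "none")

    def test_single_event(self):
        rec = composite_endpoint([("ventricular_tachyarrhythmia", 6.0)], 24.0)
        assert (rec.label, rec.time_months) == ("ventricular_tachyarrhythmia", 6.0)

    @pytest.mark.parametrize(
        "events, match",
        [
            ([("cardiac_death", -1.0)], "negative"),
            ([("cardiac_death", 30.0)], "after end"),
            ([("stroke", 1.0)], "unknown event"),
        ],
    )
    def test_invalid_inputs(self, events, match):
        with pytest.raises(StatsError, match=match):
            composite_endpoint(events, 24.0)

    def test_endpoint_table_hf_secondary(self):
        cohort = pd.DataFrame(
            {
                "id": ["a", "b", "c"],
                "followup_months": [10.0, 20.0, 30.0],
                "event": ["cardiac_death", "hf_hospitalization", "none"],
            }
        )
        comp = endpoint_table(cohort, "composite")
        hf = endpoint_table(cohort, "hf")
        assert comp.status.tolist() == [1, 1, 0]
        assert hf.status.tolist() == [0, 1, 0]


class TestKaplanMeier:
    def test_hand_computed_product_limit(self):
        # events at 1, 2; censor at 3; event at 4: S(2) = (3/4)(2/3) = 0.5
        km = km_estimate([1, 2, 3, 4], [1, 1, 0, 1])
        assert km.at(2.0) == pytest.approx(0.5)
        assert km.at(0.5) == 1.0

    def test_no_events_flat_curve(self):
        km = km_estimate([5, 6, 7], [0, 0, 0])
        assert km.at(100.0) == 1.0

    def test_all_events_at_one_time(self):
        km = km_estimate([1, 1, 1], [1, 1, 1])
        assert km.at(1.0) == 0.0

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, 50)
        km = km_estimate(t, np.ones(50))
        for q in (2.0, 5.0, 12.0):
            assert km.at(q) == pytest.approx((t > q).mean())

    def test_median_followup_reverse_km(self):
        # censoring-distribution KM drops to 0.5 at t=15 (events at 5, 10 are
        # censored observations for the reverse curve)
        km = km_estimate([5, 10, 15, 20], [1, 1, 0, 0])
        assert km.median_followup == pytest.approx(15.0)


class TestLogrank:
    def test_identical_groups_null(self):
        t, e = [1, 2, 3, 4, 5], [1, 0, 1, 0, 1]
        chi2, p = logrank_test(t, e, t, e)
        assert chi2 == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_empty_group_is_error(self):
        with pytest.raises(StatsError):
            logrank_test([], [], [1], [1])

    def test_agrees_with_independent_implementation(self):
        # dual route: lifelines-based API vs our own vectorized statistic
        rng = np.random.default_rng(7)
        ta = rng.exponential(10, 40).round(1)
        tb = rng.exponential(6, 35).round(1)
        ea = rng.integers(0, 2, 40)
        eb = rng.integers(0, 2, 35)
        chi2, _ = logrank_test(ta, ea, tb, eb)
        times = np.concatenate([ta, tb])
        events = np.concatenate([ea, eb]).astype(float)
        group = np.concatenate([np.ones(40), np.zeros(35)]).astype(bool)
        assert chi2 == pytest.approx(_logrank_chi2(times, events, group), rel=1e-6)


def _brute_force_cox_beta(times, events, x):
    """Independent oracle: maximize the (no-ties) Cox partial likelihood."""

    def neg_pl(beta):
        order = np.argsort(times)
        t, e, xx = times[order], events[order], x[order]
        ll = 0.0
        for i in range(len(t)):
            if e[i]:
                risk = xx[i:]  # everyone with time >= t_i
                ll += beta * xx[i] - np.log(np.exp(beta * risk).sum())
        return -ll

    return minimize_scalar(neg_pl, bounds=(-5, 5), method="bounded", options={"xatol": 1e-10}).x


class TestCox:
    def test_binary_covariate_matches_brute_force_partial_likelihood(self):
        times = np.array([2.0, 3.1, 4.7, 5.3, 6.9, 8.2, 9.0, 11.5, 12.3, 14.8])
        events = np.array([1, 1, 0, 1, 1, 0, 1, 1, 0, 1])
        x = np.array([1.0, 1, 0, 1, 0, 1, 0, 0, 1, 0])
        rec = pd.DataFrame({"time_months": times, "status": events, "x": x})
        fit = cox_fit(rec, ["x"])
        assert fit.coefficients["x"] == pytest.approx(
            _brute_force_cox_beta(times, events, x), abs=1e-3
        )

    def test_constant_covariate_rejected(self):
        rec = pd.DataFrame(
            {"time_months": [1.0, 2, 3, 4], "status": [1, 1, 1, 0], "x": [2.0, 2, 2, 2]}
        )
        with pytest.raises(StatsError, match="constant"):
            cox_fit(rec, ["x"])

    def test_perfectly_concordant_score_c_one(self):
        t = np.arange(1.0, 21.0)
        rec = pd.DataFrame({"time_months": t, "status": np.ones(20), "x": -t})
        fit = cox_fit(rec, ["x"])
        assert fit.c_statistic == pytest.approx(1.0)

    def test_anticoncordant_c_is_complement(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 60)
        x = rng.normal(size=60)
        rec = pd.DataFrame({"time_months": t, "status": np.ones(60), "x": x})
        from lifelines.utils import concordance_index

        c = concordance_index(t, -x)
        assert concordance_index(t, x) == pytest.approx(1.0 - c)

    def test_order_invariance(self):
        co = generate_cohort(n_subjects=400, seed=11)
        ep = endpoint_table(co)
        rec = pd.concat([ep[["time_months", "status"]], co[["rvef_3d"]]], axis=1)
        fit = cox_fit(rec, ["rvef_3d"])
        perm = rec.sample(frac=1.0, random_state=1).reset_index(drop=True)
        fit_perm = cox_fit(perm, ["rvef_3d"])
        assert fit_perm.coefficients["rvef_3d"] == pytest.approx(
            fit.coefficients["rvef_3d"], rel=1e-8
        )


class TestNestedLRT:
    def _records(self):
        co = generate_cohort(n_subjects=500, seed=21)
        ep = endpoint_table(co)
        return pd.concat(
            [ep[["time_months", "status"]], co[["age", "rvef_3d", "lvef_3d"]]], axis=1
        )

    def test_identical_models_zero_delta(self):
        rec = self._records()
        fit = cox_fit(rec, ["age"])
        delta, df, p = nested_lrt(fit, fit)
        assert (delta, df, p) == (0.0, 0, 1.0)

    def test_adding_planted_effect_is_significant(self):
        rec = self._records()
        small = cox_fit(rec, ["age"])
        large = cox_fit(rec, ["age", "rvef_3d"])
        delta, df, p = nested_lrt(small, large)
        assert df == 1 and delta > 0 and p < 0.001

    def test_non_nested_rejected(self):
        rec = self._records()
        with pytest.raises(StatsError, match="nested"):
            nested_lrt(cox_fit(rec, ["age"]), cox_fit(rec, ["rvef_3d", "lvef_3d"]))


class TestEffectSizes:
    def test_nnt_closed_forms(self):
        assert nnt_binary(0.6, 0.1) == pytest.approx(2.0)
        assert nnt_binary(0.3, 0.3) == float("inf")
        assert nnt_continuous(0.75) == pytest.approx(2.0)
        assert nnt_continuous(0.5) == float("inf")

    def test_auc_orientation_free(self):
        y = np.array([0, 0, 1, 1])
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert auc(x, y) == pytest.approx(1.0)
        assert auc(-x, y) == pytest.approx(1.0)


class TestDichotomize:
    def test_tie_goes_to_upper_group(self):
        low = dichotomize([44.0, 45.0, 46.0], 45.0, "<")
        assert low.tolist() == [True, False, False]

    def test_median_split_near_balanced(self):
        v = np.arange(11.0)
        low = dichotomize(v, float(np.median(v)), "<")
        assert abs(int(low.sum()) - int((~low).sum())) <= 1

    def test_greater_direction(self):
        high = dichotomize([30.0, 34.0, 40.0], 34.0, ">")
        assert high.tolist() == [False, False, True]


class TestImageQuality:
    def test_all_complete_is_good(self):
        q = image_quality_score([1.0] * 18)
        assert (q.total, q.category, q.excluded) == (18.0, "good", False)

    def test_mixed_fair(self):
        q = image_quality_score([1.0] * 12 + [0.5] * 6)
        assert (q.total, q.category) == (15.0, "fair")

    def test_all_partial_is_extremely_poor_and_excluded(self):
        q = image_quality_score([0.5] * 18)
        assert (q.total, q.category, q.excluded) == (9.0, "extremely_poor", True)

    @pytest.mark.parametrize("scores", [[1.0] * 17, [1.0] * 19, [0.3] + [1.0] * 17])
    def test_invalid_inputs_rejected(self, scores):
        with pytest.raises(SchemaError):
            image_quality_score(scores)

    @given(st.lists(st.sampled_from([0.0, 0.5, 1.0]), min_size=18, max_size=18))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_category_consistent_with_total(self, scores):
        q = image_quality_score(scores)
        assert q.total == sum(scores)
        bounds = {"good": (16, 18), "fair": (13, 16), "poor": (10, 13), "extremely_poor": (0, 10)}
        lo, hi = bounds[q.category]
        assert lo <= q.total <= hi
        if q.category != "good":
            assert q.total < hi
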