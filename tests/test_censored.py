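import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import km_restricted_mean_oracle, logrank_oracle
from mircad._rng import substream
from mircad.censored import (
    CensoredVector,
    bh_adjust,
    censor_nondetects,
    fold_change,
    km_restricted_mean,
    logrank_test,
    run_case_control,
)
from mircad.ct import DeltaCtMatrix


def _cv(values, censored=None, group=None):
    values = np.asarray(values, dtype=float)
    censored = np.zeros(len(values), bool) if censored is None else np.asarray(censored, bool)
    group = np.zeros(len(values)) if group is None else np.asarray(group)
    return CensoredVector(values, censored, group)


class TestCensorNondetects:
    def test_missing_pinned_at_max_observed(self):
        cv = censor_nondetects(np.array([-1.0, 0.0, 2.0, np.nan]))
        assert cv.value[3] == 2.0 and cv.censored[3]
        assert not cv.censored[:3].any()

    def test_no_missing_unchanged(self):
        cv = censor_nondetects(np.array([1.0, 2.0, 3.0]))
        assert not cv.censored.any()
        np.testing.assert_array_equal(cv.value, [1, 2, 3])

    def test_single_observed_pins_everything_there(self):
        cv = censor_nondetects(np.array([np.nan, 1.5, np.nan]))
        np.testing.assert_array_equal(cv.value, [1.5, 1.5, 1.5])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            censor_nondetects(np.array([np.nan, np.nan]))


class TestKMRestrictedMean:
    def test_no_censoring_equals_arithmetic_mean(self):
        assert km_restricted_mean(_cv([1.0, 2.0, 3.0])) == pytest.approx(2.0)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=30))
    def test_no_censoring_equals_mean_property(self, values):
        cv = _cv(values)
        assert km_restricted_mean(cv) == pytest.approx(np.mean(values), abs=1e-9)

    def test_hand_computed_with_top_value_censored(self):
        # values (1, 2, 3), the 3 censored: S drops 1 -> 2/3 at 1 -> 1/3 at 2,
        # restricted mean = 1 + 2/3*1 + 1/3*1 = 2
        assert km_restricted_mean(_cv([1, 2, 3], [False, False, True])) == pytest.approx(2.0)

    def test_all_equal_values(self):
        assert km_restricted_mean(_cv([4, 4, 4], [False, True, True])) == pytest.approx(4.0)

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError):
            km_restricted_mean(_cv([1, 2], [True, True]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_mass_redistribution_oracle(self, seed):
        rng = substream(seed, "km-oracle")
        n = int(rng.integers(3, 25))
        values = np.round(rng.normal(0, 2, n), 1)  # rounding forces ties
        censored = rng.random(n) < 0.3
        if censored.all():
            censored[0] = False
        got = km_restricted_mean(_cv(values, censored))
        want = km_restricted_mean_oracle(values, censored)
        assert got == pytest.approx(want, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_lifelines_product_limit(self, seed):
        from lifelines import KaplanMeierFitter
        from lifelines.utils import restricted_mean_survival_time

        rng = substream(seed, "km-lifelines")
        values = rng.normal(5, 1, 30)
        censored = rng.random(30) < 0.25
        censored[np.argmin(values)] = False
        shift = values.min()
        kmf = KaplanMeierFitter().fit(values - shift, event_observed=~censored)
        want = shift + restricted_mean_survival_time(kmf, t=values.max() - shift)
        got = km_restricted_mean(_cv(values, censored))
        assert got == pytest.approx(want, abs=1e-8)


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        v = _cv([1, 2, 3, 1, 2, 3], group=["a"] * 3 + ["b"] * 3)
        chisq, p = logrank_test(v)
        assert chisq == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_hand_enumeration_oracle(self, seed):
        rng = substream(seed, "lr-oracle")
        n = int(rng.integers(6, 30))
        values = np.round(rng.normal(0, 1, n), 1)
        censored = rng.random(n) < 0.2
        group = rng.random(n) < 0.5
        a = values[group]
        if len(a) == 0 or len(a) == n or censored[group].all() or censored[~group].all():
            pytest.skip("degenerate draw")
        labels = np.where(group, "a", "b")
        got_chisq, _ = logrank_test(_cv(values, censored, labels))
        want = logrank_oracle(values, censored, group)
        assert got_chisq == pytest.approx(want, rel=1e-6)

    def test_shift_invariance(self):
        rng = substream(0, "lr-shift")
        values = rng.normal(0, 1, 40)
        censored = rng.random(40) < 0.2
        labels = np.repeat(["a", "b"], 20)
        _, p0 = logrank_test(_cv(values, censored, labels))
        _, p1 = logrank_test(_cv(values + 17.3, censored, labels))
        assert p0 == pytest.approx(p1, rel=1e-9)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test(_cv([1, 2, 3], group=["a"] * 3))


class TestFoldChange:
    def test_equal_means_give_unity(self):
        assert fold_change(1.3, 1.3) == pytest.approx(1.0)

    def test_one_cycle_lower_doubles(self):
        assert fold_change(-1.0, 0.0) == pytest.approx(2.0)

    def test_direction_matches_upregulation(self):
        # a case mean log2(4.85) cycles below control means FC 4.85
        assert fold_change(-np.log2(4.85), 0.0) == pytest.approx(4.85)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(-5, 5), st.floats(-5, 5))
    def test_antisymmetric_under_group_swap(self, a, b):
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)


class TestBHAdjust:
    def test_step_up_on_fixed_vector(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_all_equal_stay_equal(self):
        np.testing.assert_allclose(bh_adjust([0.04] * 5), [0.04] * 5)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_adjusted_monotone_and_at_least_raw(self, ps):
        ps = np.asarray(ps)
        adj = bh_adjust(ps)
        assert (adj >= ps - 1e-12).all() and (adj <= 1 + 1e-12).all()
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestRunCaseControl:
    def _delta(self, seed, n=60, m=6, fc=0.0):
        rng = substream(seed, "cc")
        vals = rng.normal(0, 1, size=(2 * n, m))
        vals[:n, 0] -= fc
        df = pd.DataFrame(vals, index=[f"s{i}" for i in range(2 * n)],
                          columns=[f"m{j}" for j in range(m)])
        groups = pd.Series(["case"] * n + ["control"] * n, index=df.index)
        return DeltaCtMatrix(values=df, per_sample_reference=df.mean(axis=1)), groups

    def test_null_yields_no_adjusted_hits(self):
        delta, groups = self._delta(0)
        res = run_case_control(delta, groups)
        assert (res["p_adj"] < 0.05).sum() == 0

    def test_all_mirnas_reported_regardless_of_significance(self):
        delta, groups = self._delta(1, m=14)
        res = run_case_control(delta, groups)
        assert len(res) == 14
        assert (res["status"] == "ok").all()

    def test_planted_effect_detected_with_correct_fold_change(self):
        delta, groups = self._delta(2, n=200, fc=1.0)
        res = run_case_control(delta, groups).set_index("mirna")
        assert res.loc["m0", "fold_change"] == pytest.approx(2.0, rel=0.25)
        assert res.loc["m0", "p_adj"] < 0.01

    def test_failed_mirna_flagged_not_fatal(self):
        delta, groups = self._delta(3, n=20, m=3)
        # all-censored-in-one-group scenario: constant column means
        # every observation ties; make case group fully "missing"
        vals = delta.values.copy()
        vals.loc[groups == "case", "m2"] = np.nan
        vals.loc[groups == "control", "m2"] = 1.0
        delta2 = DeltaCtMatrix(values=vals, per_sample_reference=delta.per_sample_reference)
        res = run_case_control(delta2, groups).set_index("mirna")
        assert res.loc["m2", "status"].startswith("failed")
        assert res.loc[["m0", "m1"], "status"].eq("ok").all()
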