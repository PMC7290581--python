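import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from mircad._rng import substream
from mircad.coxcc import assign_casecohort_weights, fit_weighted_cox, run_mirna_scan


def _records(ids, times, events, subcohort, **covs):
    df = pd.DataFrame({"id": ids, "time": times, "event": events,
                       "in_subcohort": subcohort})
    for k, v in covs.items():
        df[k] = v
    return df


def weighted_breslow_loglik(beta, df, term):
    """Independent weighted Cox partial log-likelihood with late entry."""
    x = df[term].to_numpy(float)
    w = df["weight"].to_numpy(float)
    entry = df["entry"].to_numpy(float)
    stop = df["stop"].to_numpy(float)
    ev = df["event"].to_numpy(bool)
    ll = 0.0
    for i in np.flatnonzero(ev):
        t = stop[i]
        risk = (entry < t) & (stop >= t)
        ll += w[i] * (beta * x[i] - np.log(np.sum(w[risk] * np.exp(beta * x[risk]))))
    return ll


class TestWeights:
    def test_full_sampling_gives_unit_weights(self):
        rec = _records(["a", "b", "c"], [2.0, 3.0, 4.0], [1, 0, 0],
                       [True, True, True], x=[1.0, 0.0, 1.0])
        w = assign_casecohort_weights(rec, sampling_fraction=1.0)
        assert (w["weight"] == 1.0).all()

    def test_quarter_subcohort_gives_weight_four(self):
        rec = _records(["a", "b"], [2.0, 3.0], [0, 1], [True, False],
                       x=[0.0, 1.0])
        w = assign_casecohort_weights(rec, sampling_fraction=0.25)
        assert w.loc[w["id"] == "a", "weight"].iloc[0] == pytest.approx(4.0)
        assert w.loc[(w["id"] == "b") & (w["event"] == 1), "weight"].iloc[0] == 1.0

    def test_case_enters_just_before_failure(self):
        rec = _records(["a", "b"], [5.0, 8.0], [1, 0], [False, True], x=[1.0, 0.0])
        w = assign_casecohort_weights(rec, sampling_fraction=0.5)
        row = w[(w["id"] == "a") & (w["event"] == 1)].iloc[0]
        assert 0 < row["entry"] < row["stop"] == 5.0

    def test_record_neither_event_nor_subcohort_rejected(self):
        rec = _records(["a"], [2.0], [0], [False], x=[0.0])
        with pytest.raises(ValueError):
            assign_casecohort_weights(rec, sampling_fraction=0.5)

    def test_prentice_subcohort_unweighted(self):
        rec = _records(["a", "b"], [2.0, 3.0], [0, 1], [True, False], x=[0.0, 1.0])
        w = assign_casecohort_weights(rec, sampling_fraction=0.25, scheme="prentice")
        assert (w["weight"] == 1.0).all()


class TestFitWeightedCox:
    def _toy(self, seed=0, n=6):
        rng = substream(seed, "cox-toy")
        times = np.sort(rng.uniform(1, 10, n))  # distinct: no ties
        events = np.array([1, 0, 1, 0, 1, 0][:n])
        x = rng.normal(0, 1, n)
        return _records([f"r{i}" for i in range(n)], times, events,
                        [True] * n, x=x)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_partial_likelihood_maximizer_on_toys(self, seed):
        rec = self._toy(seed)
        w = assign_casecohort_weights(rec, sampling_fraction=1.0)
        fit = fit_weighted_cox(w, ["x"])
        opt = minimize_scalar(
            lambda b: -weighted_breslow_loglik(b, w, "x"), bounds=(-5, 5),
            method="bounded", options={"xatol": 1e-10},
        )
        assert fit.coefficients["x"] == pytest.approx(opt.x, abs=1e-3)

    def test_weighted_toy_matches_grid_oracle(self):
        # subcohort weighting changes the maximizer; oracle must track it
        rec = self._toy(7)
        rec["in_subcohort"] = ~rec["event"].astype(bool)  # cases outside subcohort
        w = assign_casecohort_weights(rec, sampling_fraction=0.5)
        fit = fit_weighted_cox(w, ["x"])
        opt = minimize_scalar(
            lambda b: -weighted_breslow_loglik(b, w, "x"), bounds=(-5, 5),
            method="bounded", options={"xatol": 1e-10},
        )
        assert fit.coefficients["x"] == pytest.approx(opt.x, abs=1e-3)

    def test_duplicated_records_equal_doubled_weights(self):
        rec = self._toy(3)
        w1 = assign_casecohort_weights(rec, sampling_fraction=1.0)
        dup = pd.concat([w1, w1.assign(id=w1["id"] + "_copy")], ignore_index=True)
        doubled = w1.assign(weight=w1["weight"] * 2)
        f_dup = fit_weighted_cox(dup, ["x"])
        f_dbl = fit_weighted_cox(doubled, ["x"])
        assert f_dup.coefficients["x"] == pytest.approx(f_dbl.coefficients["x"], abs=1e-6)

    def test_matches_lifelines_without_ties(self):
        # with distinct event times Efron and Breslow tie handling coincide,
        # so lifelines (Efron) is an independent cross-check
        from lifelines import CoxPHFitter

        rng = substream(11, "cox-ll")
        n = 120
        df = pd.DataFrame({
            "time": rng.exponential(6, n) + 0.01,
            "event": (rng.random(n) < 0.4).astype(int),
            "x": rng.normal(0, 1, n),
            "z": rng.normal(0, 1, n),
        })
        rec = _records([f"r{i}" for i in range(n)], df["time"], df["event"],
                       [True] * n, x=df["x"], z=df["z"])
        w = assign_casecohort_weights(rec, sampling_fraction=1.0)
        fit = fit_weighted_cox(w, ["x", "z"])
        cph = CoxPHFitter().fit(df, duration_col="time", event_col="event")
        for term in ("x", "z"):
            assert fit.coefficients[term] == pytest.approx(
                cph.params_[term], abs=1e-5)
        surv = cph.predict_survival_function(df[["x", "z"]], times=[5.0])
        risk_ll = 1.0 - surv.iloc[0].to_numpy(float)
        risk_us = fit.predict_risk(df[["x", "z"]], horizon=5.0)
        np.testing.assert_allclose(risk_us, risk_ll, atol=1e-5)

    def test_negating_covariate_negates_coefficient(self):
        rec = self._toy(4)
        w = assign_casecohort_weights(rec, sampling_fraction=1.0)
        f1 = fit_weighted_cox(w, ["x"])
        f2 = fit_weighted_cox(w.assign(x=-w["x"]), ["x"])
        assert f1.coefficients["x"] == pytest.approx(-f2.coefficients["x"], abs=1e-8)

    def test_null_covariate_near_zero(self):
        rng = substream(5, "cox-null")
        n = 400
        rec = _records([f"r{i}" for i in range(n)],
                       rng.exponential(5, n) + 0.01,
                       (rng.random(n) < 0.3).astype(int),
                       [True] * n, x=rng.normal(0, 1, n))
        w = assign_casecohort_weights(rec, sampling_fraction=1.0)
        fit = fit_weighted_cox(w, ["x"])
        assert abs(fit.coefficients["x"]) < 3 * fit.robust_se["x"] + 0.05
        lo, hi = fit.ci95["x"]
        assert lo <= fit.hr["x"] <= hi
        assert fit.robust_se["x"] > 0

    def test_collinear_terms_detected(self):
        rec = self._toy(6)
        rec["x2"] = 2 * rec["x"]
        w = assign_casecohort_weights(rec, sampling_fraction=1.0)
        with pytest.raises(ValueError, match="collinear"):
            fit_weighted_cox(w, ["x", "x2"])

    def test_no_events_rejected(self):
        rec = _records(["a", "b"], [1.0, 2.0], [0, 0], [True, True], x=[0.0, 1.0])
        w = assign_casecohort_weights(rec, sampling_fraction=1.0)
        with pytest.raises(ValueError, match="no events"):
            fit_weighted_cox(w, ["x"])


class TestMirnaScan:
    def _cohort_records(self, seed=0, n=300, n_mirna=3):
        rng = substream(seed, "scan")
        df = _records(
            [f"r{i}" for i in range(n)],
            rng.exponential(8, n) + 0.01,
            (rng.random(n) < 0.25).astype(int),
            [True] * n,
            age=rng.normal(55, 10, n),
            sex=rng.integers(0, 2, n).astype(float),
        )
        for j in range(n_mirna):
            df[f"miR-{j}"] = rng.normal(0, 1, n)
        return df

    def test_one_row_per_mirna_per_adjustment_set(self):
        df = self._cohort_records()
        res = run_mirna_scan(df, [f"miR-{j}" for j in range(3)],
                             sampling_fraction=1.0)
        assert len(res) == 6
        assert set(res["model"]) == {"base", "full"}

    def test_constant_mirna_flagged_zero_variance(self):
        df = self._cohort_records()
        df["miR-0"] = 1.0
        res = run_mirna_scan(df, ["miR-0"], sampling_fraction=1.0)
        assert res["status"].str.contains("zero variance").all()

    def test_too_few_complete_cases_flagged(self):
        df = self._cohort_records()
        df.loc[df.index[5:], "miR-1"] = np.nan
        res = run_mirna_scan(df, ["miR-1"], sampling_fraction=1.0)
        assert res["status"].str.contains("complete cases").all()
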