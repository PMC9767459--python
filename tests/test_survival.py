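"""Cox partial-likelihood fitting against brute-force oracles, and
Kaplan-Meier step functions."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from mitopersona import synthdata
from mitopersona.survival import ConvergenceError, fit_cox, kaplan_meier


def breslow_loglik_oracle(beta, time, event, x):
    """Hand-coded Breslow partial log-likelihood with explicit risk-set
    loops; single covariate."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        deaths = (time == t) & (event == 1)
        risk = time >= t
        d = deaths.sum()
        ll += beta * x[deaths].sum() - d * np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def brute_force_cox(time, event, x):
    """Coarse grid scan followed by golden-section refinement."""
    grid = np.linspace(-5, 5, 201)
    vals = [breslow_loglik_oracle(b, time, event, x) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    res = optimize.minimize_scalar(
        lambda b: -breslow_loglik_oracle(b, time, event, x),
        bracket=(b0 - 0.1, b0, b0 + 0.1),
        method="golden",
        options={"xtol": 1e-10},
    )
    return res.x


TINY_FIXTURES = [
    # (time, event, covariate)
    ([1.0, 2.0, 3.0, 4.0, 5.0], [1, 1, 0, 1, 0], [0.5, -1.0, 0.0, 2.0, 1.0]),
    ([2.0, 2.0, 3.0, 4.0, 5.0, 6.0], [1, 1, 1, 0, 1, 1], [1.0, 0.0, -1.0, 0.5, 2.0, -0.5]),
    ([1.0, 1.5, 2.5, 3.5], [1, 0, 1, 1], [0.0, 1.0, -1.0, 0.5]),
    ([1.0, 2.0, 2.0, 3.0, 4.0], [1, 1, 1, 1, 0], [0.3, -0.2, 0.8, -1.0, 0.1]),
]


class TestCoxFit:
    @pytest.mark.parametrize("time,event,x", TINY_FIXTURES)
    def test_matches_brute_force_oracle(self, time, event, x):
        df = pd.DataFrame({"time": time, "dead": event, "x": x})
        fit = fit_cox(df, covariates=["x"])
        oracle = brute_force_cox(np.array(time), np.array(event), np.array(x))
        assert fit.coefficients["x"] == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("time,event,x", TINY_FIXTURES)
    def test_loglik_at_optimum_beats_null(self, time, event, x):
        df = pd.DataFrame({"time": time, "dead": event, "x": x})
        fit = fit_cox(df, covariates=["x"])
        null_ll = breslow_loglik_oracle(0.0, np.array(time), np.array(event), np.array(x))
        assert fit.loglik >= null_ll - 1e-10

    def test_matches_lifelines_without_ties(self, rng):
        from lifelines import CoxPHFitter

        n = 300
        x1, x2 = rng.normal(size=n), rng.normal(size=n)
        df = synthdata.exponential_survival(0.5 * x1 - 0.3 * x2, 0.1, 20.0, rng)
        df["x1"], df["x2"] = x1, x2
        fit = fit_cox(df, covariates=["x1", "x2"])
        cph = CoxPHFitter().fit(df, duration_col="time", event_col="dead")
        # no tied event times, so Efron (lifelines) and Breslow coincide
        assert fit.coefficients["x1"] == pytest.approx(cph.params_["x1"], abs=1e-4)
        assert fit.coefficients["x2"] == pytest.approx(cph.params_["x2"], abs=1e-4)
        assert fit.se["x1"] == pytest.approx(cph.standard_errors_["x1"], abs=1e-4)

    def test_rank_based_time_invariance(self, rng):
        n = 200
        x = rng.normal(size=n)
        df = synthdata.exponential_survival(0.4 * x, 0.1, 30.0, rng)
        df["x"] = x
        base = fit_cox(df, covariates=["x"])
        warped = df.assign(time=df["time"] ** 2)  # strictly increasing map
        assert fit_cox(warped, covariates=["x"]).coefficients["x"] == pytest.approx(
            base.coefficients["x"], abs=1e-8
        )

    def test_covariate_centering_invariance(self, rng):
        n = 150
        x = rng.normal(size=n)
        df = synthdata.exponential_survival(0.3 * x, 0.1, 30.0, rng)
        df["x"] = x
        shifted = df.assign(x=df["x"] + 1000.0)
        a = fit_cox(df, covariates=["x"]).coefficients["x"]
        b = fit_cox(shifted, covariates=["x"]).coefficients["x"]
        assert a == pytest.approx(b, abs=1e-6)

    def test_planted_positive_log_hazard_detected(self, rng):
        n = 5000
        vulnerability_like = rng.normal(size=n)
        df = synthdata.exponential_survival(0.3 * vulnerability_like, 0.05, 15.0, rng)
        df["facet"] = vulnerability_like
        fit = fit_cox(df, covariates=["facet"])
        assert fit.coefficients["facet"] > 0
        assert fit.p["facet"] < 0.01

    def test_null_covariate_type_i_error(self):
        hits = 0
        n_rep = 200
        for i in range(n_rep):
            r = np.random.default_rng(10_000 + i)
            x = r.normal(size=100)
            df = synthdata.exponential_survival(np.zeros(100), 0.08, 15.0, r)
            df["x"] = x
            if fit_cox(df, covariates=["x"]).p["x"] < 0.05:
                hits += 1
        assert 0.02 <= hits / n_rep <= 0.10

    def test_no_events_raises(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "dead": [0, 0], "x": [0.1, 0.2]})
        with pytest.raises(ValueError, match="no events"):
            fit_cox(df, covariates=["x"])

    def test_perfect_separation_raises(self):
        # covariate orders subjects exactly by event time: monotone likelihood
        df = pd.DataFrame(
            {
                "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "dead": [1, 1, 1, 1, 1, 1],
                "x": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            }
        )
        with pytest.raises(ConvergenceError):
            fit_cox(df, covariates=["x"])


class TestKaplanMeier:
    def test_all_events_distinct_times(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0, 4.0], "dead": [1, 1, 1, 1]})
        km = kaplan_meier(df)["all"]
        assert np.allclose(km["survival"], [0.75, 0.5, 0.25, 0.0])
        assert list(km["at_risk"]) == [4, 3, 2, 1]

    def test_all_censored_flat_at_one(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "dead": [0, 0, 0]})
        km = kaplan_meier(df)["all"]
        assert np.allclose(km["survival"], 1.0)

    def test_censoring_does_not_drop_curve(self):
        df = pd.DataFrame({"time": [1.0, 2.0, 3.0], "dead": [1, 0, 1]})
        km = kaplan_meier(df)["all"].set_index("time")
        assert km.loc[2.0, "survival"] == km.loc[1.0, "survival"]

    def test_survival_non_increasing_from_one(self, older_cohort_table):
        km = kaplan_meier(older_cohort_table)["all"]
        s = km["survival"].to_numpy()
        assert s[0] <= 1.0
        assert np.all(np.diff(s) <= 1e-12)

    def test_empty_group_omitted_with_warning(self):
        df = pd.DataFrame(
            {"time": [1.0, 2.0], "dead": [1, 0], "g": ["a", "a"]}
        )
        df["g"] = pd.Categorical(df["g"], categories=["a", "b"])
        with pytest.warns(UserWarning, match="no usable records"):
            km = kaplan_meier(df, group_col="g")
        assert set(km) == {"a"}

    def test_curves_ordered_by_pmi_with_planted_gradient(self):
        """A mortality gradient across PMI levels should order the five
        curves at the median follow-up time in nearly all replicates."""
        ordered = 0
        n_rep = 40
        for i in range(n_rep):
            cfg = synthdata.SimConfig(
                n_participants=4000,
                seed=40_000 + i,
                direct_c_prime=-0.1,
                baseline_mortality=0.55,
            )
            data = synthdata.generate_cohort(cfg).data
            km = kaplan_meier(data, group_col="pmi_true")
            t_mid = cfg.followup_years / 2
            surv = []
            for g in sorted(km, key=float):
                curve = km[g]
                below = curve[curve["time"] <= t_mid]
                surv.append(below["survival"].iloc[-1] if len(below) else 1.0)
            if np.all(np.diff(surv) > 0):
                ordered += 1
        assert ordered >= 0.85 * n_rep
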