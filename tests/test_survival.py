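"""Cox solver, Schoenfeld PH test, and time-interaction fallback.

The in-package Newton solver is checked against three independent routes:
a brute-force maximization of the partial likelihood on tiny datasets, the
closed-form score equation of the 3-subject toy, and lifelines as an
external reference implementation.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from exposcan import survival as sv
from exposcan.errors import ConstantCovariateError, MonotoneLikelihoodError

from conftest import survival_frame


def partial_loglik_brute(beta, time, event, x):
    """Independent oracle: Efron partial log-likelihood by direct summation."""
    ll = 0.0
    for ut in np.unique(time[event == 1]):
        deaths = (time == ut) & (event == 1)
        at_risk = time >= ut
        d = deaths.sum()
        eta_d = beta * x[deaths]
        s_risk = np.exp(beta * x[at_risk]).sum()
        s_d = np.exp(eta_d).sum()
        ll += eta_d.sum()
        for l in range(d):
            ll -= np.log(s_risk - (l / d) * s_d)
    return ll


class TestFitCox:
    def test_three_subject_toy_matches_closed_form(self):
        """Score equation for times (1,2,3) all events, x=(1,0,1) solves to
        exp(2beta) = 1/2, i.e. beta = -ln(2)/2."""
        df = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 1], "x": [1, 0, 1]})
        fit = sv.fit_cox(df, "x", adjusters=())
        assert fit.beta[0] == pytest.approx(-np.log(2) / 2, abs=1e-6)
        assert fit.hr[0] == pytest.approx(1 / np.sqrt(2), abs=1e-6)

    def test_three_subject_toy_matches_grid_search_oracle(self):
        df = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 1], "x": [1, 0, 1]})
        fit = sv.fit_cox(df, "x", adjusters=())
        res = optimize.minimize_scalar(
            lambda b: -partial_loglik_brute(
                b, df["time"].to_numpy(), df["event"].to_numpy(), df["x"].to_numpy()
            ),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-4)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_small_sample_oracle_equivalence(self, seed):
        """On <=8 subjects without ties the fitted log-HR matches brute-force
        maximization of the partial likelihood to 1e-4."""
        rng = np.random.default_rng(seed)
        n = 8
        time = rng.permutation(np.arange(1.0, n + 1))
        event = np.ones(n)
        event[rng.integers(0, n)] = 0
        x = rng.normal(size=n)
        df = pd.DataFrame({"time": time, "event": event, "x": x})
        try:
            fit = sv.fit_cox(df, "x", adjusters=())
        except MonotoneLikelihoodError:
            pytest.skip("separated draw")
        res = optimize.minimize_scalar(
            lambda b: -partial_loglik_brute(b, time, event, x),
            bounds=(-8, 8),
            method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.beta[0] == pytest.approx(res.x, abs=1e-4)

    def test_matches_lifelines_reference(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 2000
        df = survival_frame(rng, n, log_hr=0.4)
        df["z"] = rng.standard_normal(n)
        fit = sv.fit_cox(df, ["x", "z"], adjusters=())
        cph = lifelines.CoxPHFitter().fit(df, duration_col="time", event_col="event")
        np.testing.assert_allclose(fit.beta, cph.params_[["x", "z"]], atol=1e-5)
        np.testing.assert_allclose(
            fit.se, cph.standard_errors_[["x", "z"]], atol=1e-5
        )
        assert fit.log_likelihood == pytest.approx(cph.log_likelihood_, abs=1e-4)

    def test_constant_covariate_errors(self):
        df = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 0], "x": [1, 1, 1]})
        with pytest.raises(ConstantCovariateError):
            sv.fit_cox(df, "x", adjusters=())

    def test_monotone_likelihood_named(self):
        df = pd.DataFrame({"time": [1, 2], "event": [1, 1], "x": [1, 0]})
        with pytest.raises(MonotoneLikelihoodError) as err:
            sv.fit_cox(df, "x", adjusters=())
        assert err.value.covariate == "x"

    def test_time_shift_invariance(self, rng):
        """Cox estimates depend only on the rank order of times."""
        df = survival_frame(rng, 500, log_hr=0.5)
        fit1 = sv.fit_cox(df, "x", adjusters=())
        df2 = df.assign(time=df["time"] + 100.0)
        fit2 = sv.fit_cox(df2, "x", adjusters=())
        assert fit1.beta[0] == pytest.approx(fit2.beta[0], abs=1e-10)

    def test_hr_and_ci_consistent_with_beta(self, rng):
        df = survival_frame(rng, 800, log_hr=0.5)
        fit = sv.fit_cox(df, "x", adjusters=())
        assert fit.hr[0] == pytest.approx(np.exp(fit.beta[0]))
        lo, hi = fit.ci[0]
        assert lo == pytest.approx(np.exp(fit.beta[0] - 1.96 * fit.se[0]), rel=1e-3)
        assert hi == pytest.approx(np.exp(fit.beta[0] + 1.96 * fit.se[0]), rel=1e-3)
        assert fit.n_events <= fit.n


class TestSchoenfeldTest:
    def test_matches_lifelines_km_transform(self, rng):
        lifelines = pytest.importorskip("lifelines")
        from lifelines.statistics import proportional_hazard_test

        df = survival_frame(rng, 1500, log_hr=0.4)
        df["z"] = rng.standard_normal(len(df))
        fit = sv.fit_cox(df, ["x", "z"], adjusters=(), ph_test=True)
        cph = lifelines.CoxPHFitter().fit(df, duration_col="time", event_col="event")
        ref = proportional_hazard_test(cph, df, time_transform="km").summary
        for term in ("x", "z"):
            assert fit.ph_pvalues[term] == pytest.approx(
                ref.loc[term, "p"], abs=5e-3
            )

    def test_detects_reversing_effect(self):
        """A covariate whose effect flips sign mid-follow-up violates PH and
        is flagged with high power at n=2000."""
        hits = 0
        reps = 10
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            n = 2000
            x = rng.binomial(1, 0.5, n)
            lam0 = 0.05
            early = rng.exponential(1.0 / (lam0 * np.exp(np.log(2) * x)))
            late = 5 + rng.exponential(1.0 / (lam0 * np.exp(-np.log(2) * x)))
            t = np.where(early <= 5, early, late)
            event = (t <= 10).astype(int)
            df = pd.DataFrame({"time": np.minimum(t, 10), "event": event, "x": x})
            fit = sv.fit_cox(df, "x", adjusters=(), ph_test=True)
            hits += fit.ph_pvalues["x"] < 0.05
        assert hits / reps > 0.8

    def test_requires_two_events(self):
        # single event on an interior covariate value: the fit is finite but
        # the PH test is undefined
        df = pd.DataFrame({"time": [1, 2, 3], "event": [1, 0, 0], "x": [0.5, 0.0, 1.0]})
        fit = sv.fit_cox(df, "x", adjusters=())
        with pytest.raises(ValueError):
            sv.schoenfeld_ph_test(fit)


class TestTimeInteraction:
    def test_zero_transform_reduces_to_plain_fit(self, rng):
        df = survival_frame(rng, 600, log_hr=0.4)
        plain = sv.fit_cox(df, "x", adjusters=())
        fit = sv.fit_cox_time_interaction(
            df, "x", adjusters=(), time_transform=lambda t: np.zeros_like(t)
        )
        assert not fit.time_interaction
        np.testing.assert_allclose(fit.beta, plain.beta, atol=1e-10)

    def test_matches_lifelines_time_varying(self, rng):
        lifelines = pytest.importorskip("lifelines")
        df = survival_frame(rng, 300, log_hr=0.3, scale=0.08)
        fit = sv.fit_cox_time_interaction(df, "x", adjusters=())
        # episodic expansion at event times, x * log(stop) as the tv column
        evt = np.sort(df.loc[df.event == 1, "time"].unique())
        rows = []
        for i, r in df.iterrows():
            start = 0.0
            for c in evt[evt <= r.time]:
                rows.append(
                    {
                        "id": i,
                        "start": start,
                        "stop": c,
                        "event": int(r.event and np.isclose(c, r.time)),
                        "x": r.x,
                        "x_gt": r.x * np.log(c),
                    }
                )
                start = c
        long = pd.DataFrame(rows)
        ctv = lifelines.CoxTimeVaryingFitter().fit(
            long, id_col="id", event_col="event", start_col="start", stop_col="stop"
        )
        assert fit.interaction_terms["gamma"] == pytest.approx(
            ctv.params_["x_gt"], abs=1e-6
        )
        tbar = df.loc[df.event == 1, "time"].mean()
        assert fit.beta[0] == pytest.approx(
            ctv.params_["x"] + ctv.params_["x_gt"] * np.log(tbar), abs=1e-6
        )

    def test_likelihood_dominates_plain_fit_under_ph_violation(self):
        rng = np.random.default_rng(7)
        n = 1500
        x = rng.binomial(1, 0.5, n)
        lam0 = 0.05
        early = rng.exponential(1.0 / (lam0 * np.exp(np.log(2) * x)))
        late = 5 + rng.exponential(1.0 / (lam0 * np.exp(-np.log(2) * x)))
        t = np.where(early <= 5, early, late)
        df = pd.DataFrame(
            {"time": np.minimum(t, 10), "event": (t <= 10).astype(int), "x": x}
        )
        plain = sv.fit_cox(df, "x", adjusters=())
        tv = sv.fit_cox_time_interaction(df, "x", adjusters=())
        assert tv.log_likelihood > plain.log_likelihood

    def test_interaction_ci_covers_zero_under_true_ph(self):
        """With a time-constant true effect, the interaction coefficient's
        95% CI should cover zero in at least 93% of replicates."""
        covered = 0
        reps = 100
        for r in range(reps):
            rng = np.random.default_rng(300 + r)
            df = survival_frame(rng, 2000, log_hr=0.4, scale=0.02)
            fit = sv.fit_cox_time_interaction(df, "x", adjusters=())
            g = fit.interaction_terms
            lo = g["gamma"] - 1.96 * g["gamma_se"]
            hi = g["gamma"] + 1.96 * g["gamma_se"]
            covered += lo <= 0 <= hi
        assert covered / reps >= 0.93
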