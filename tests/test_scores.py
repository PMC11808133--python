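"""Factor orientation, composite domain scores, tertiles, joint and
gene-environment models."""

import numpy as np
import pandas as pd
import pytest

from exposcan import genetics, scores as sc, survival as sv, synthetic as syn
from exposcan.errors import DegenerateScoreError


def sig_table(rows):
    return pd.DataFrame(rows, columns=["variable", "domain", "hr"])


def catalog_for(cols):
    return pd.DataFrame(
        [
            {
                "variable": v,
                "domain": d,
                "var_type": t,
                "modifiable": True,
                "n_instances": 1,
                "count_coded": False,
            }
            for v, d, t in cols
        ]
    )


class TestOrientFactors:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.cohort = pd.DataFrame(
            {
                "b_prot": rng.binomial(1, 0.3, 200).astype(float),
                "b_risk": rng.binomial(1, 0.4, 200).astype(float),
                "c_prot": rng.standard_normal(200),
                "c_risk": rng.standard_normal(200),
            }
        )
        self.catalog = catalog_for(
            [
                ("b_prot", "lifestyle", "binary"),
                ("b_risk", "lifestyle", "binary"),
                ("c_prot", "physical_measures", "continuous"),
                ("c_risk", "physical_measures", "continuous"),
            ]
        )
        self.sig = sig_table(
            [
                ("b_prot", "lifestyle", 0.66),
                ("b_risk", "lifestyle", 1.38),
                ("c_prot", "physical_measures", 0.98),
                ("c_risk", "physical_measures", 1.10),
            ]
        )

    def test_protective_binary_complemented(self):
        oriented, book = sc.orient_factors(self.sig, self.cohort, self.catalog)
        np.testing.assert_allclose(
            oriented["b_prot"], 1.0 - self.cohort["b_prot"]
        )
        assert book.set_index("variable").loc["b_prot", "rule"] == "complemented"

    def test_adverse_binary_unchanged(self):
        oriented, _ = sc.orient_factors(self.sig, self.cohort, self.catalog)
        np.testing.assert_allclose(oriented["b_risk"], self.cohort["b_risk"])

    def test_continuous_dichotomized_in_risk_direction(self):
        oriented, _ = sc.orient_factors(self.sig, self.cohort, self.catalog)
        med_p = np.median(self.cohort["c_prot"])
        med_r = np.median(self.cohort["c_risk"])
        np.testing.assert_allclose(
            oriented["c_prot"], (self.cohort["c_prot"] <= med_p).astype(float)
        )
        np.testing.assert_allclose(
            oriented["c_risk"], (self.cohort["c_risk"] > med_r).astype(float)
        )

    def test_result_is_binary(self):
        oriented, _ = sc.orient_factors(self.sig, self.cohort, self.catalog)
        assert set(np.unique(oriented.to_numpy())) <= {0.0, 1.0}


class TestScores:
    def test_unweighted_is_row_sum(self):
        oriented = pd.DataFrame({"a": [1.0, 0.0, 1.0], "b": [0.0, 0.0, 1.0],
                                 "c": [1.0, 0.0, 1.0]})
        np.testing.assert_allclose(
            sc.unweighted_score(oriented, ["a", "b", "c"]), [2.0, 0.0, 3.0]
        )

    def test_weighted_score_formula(self):
        """S = sum(X_k beta_k) / sum(beta_k) on a cohort where the
        within-domain Cox weights are recovered, then checked directly."""
        rng = np.random.default_rng(3)
        n = 6000
        x1 = rng.binomial(1, 0.4, n).astype(float)
        x2 = rng.binomial(1, 0.3, n).astype(float)
        lp = 0.8 * x1 + 0.4 * x2
        t = rng.exponential(1 / (0.02 * np.exp(lp)))
        cohort = pd.DataFrame(
            {
                "time": np.minimum(t, 12),
                "event": (t <= 12).astype(int),
                "x1": x1,
                "x2": x2,
            }
        )
        oriented = cohort[["x1", "x2"]]
        model = sc.weighted_score(oriented, ["x1", "x2"], cohort, "lifestyle",
                                  adjusters=())
        beta = model.betas.to_numpy()
        expected = (oriented.to_numpy() @ beta) / beta.sum()
        np.testing.assert_allclose(model.weighted, expected, atol=1e-12)
        assert model.weighted.min() >= 0 and model.weighted.max() <= 1
        # the all-risk profile scores exactly 1, the no-risk profile 0
        assert model.weighted[(x1 == 1) & (x2 == 1)].max() == pytest.approx(1.0)
        assert model.weighted[(x1 == 0) & (x2 == 0)].max() == pytest.approx(0.0)

    def test_weighted_score_invariant_to_beta_rescaling(self):
        betas = pd.Series([0.2, 0.3, 0.5], index=["a", "b", "c"])
        X = np.array([[1.0, 0, 0], [1, 1, 1], [0, 0, 0]])
        s1 = X @ betas.to_numpy() / betas.sum()
        s2 = X @ (10 * betas.to_numpy()) / (10 * betas).sum()
        np.testing.assert_allclose(s1, s2)
        assert s1[0] == pytest.approx(0.2)
        assert s1[1] == pytest.approx(1.0)
        assert s1[2] == pytest.approx(0.0)

    def test_weighted_and_unweighted_positively_correlated(self, small_cohort):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(4)
        oriented = pd.DataFrame(
            rng.binomial(1, 0.4, size=(3000, 3)).astype(float),
            columns=["a", "b", "c"],
        )
        lp = oriented.to_numpy() @ np.array([0.5, 0.4, 0.6])
        t = rng.exponential(1 / (0.02 * np.exp(lp)))
        cohort = pd.DataFrame(
            {"time": np.minimum(t, 12), "event": (t <= 12).astype(int)}
        )
        model = sc.weighted_score(
            oriented, ["a", "b", "c"], pd.concat([cohort, oriented], axis=1),
            "lifestyle", adjusters=()
        )
        rho = spearmanr(model.weighted, model.unweighted).statistic
        assert rho > 0


class TestCategorizeTertiles:
    def test_exact_split_and_labels(self):
        labels = sc.categorize_tertiles(np.arange(1.0, 10.0))
        assert (labels[:3] == "favorable").all()
        assert (labels[3:6] == "moderate").all()
        assert (labels[6:] == "unfavorable").all()

    def test_ties_go_to_lower_category(self):
        scores = np.array([0.0] * 5 + [1.0] * 4)
        labels = sc.categorize_tertiles(scores)
        assert (labels[:5] == "favorable").all()
        # determinism regardless of tie mass
        labels2 = sc.categorize_tertiles(scores)
        assert (labels == labels2).all()

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        scores = rng.standard_normal(100)
        a = sc.categorize_tertiles(scores)
        b = sc.categorize_tertiles(np.exp(scores))
        assert (a == b).all()

    def test_constant_scores_error(self):
        with pytest.raises(DegenerateScoreError):
            sc.categorize_tertiles(np.ones(10))


def _effect_cohort(seed=13, n=20_000):
    """Cohort where only the medical-history domain carries risk."""
    b = np.log(1.7)
    cfg = syn.GeneratorConfig(
        n_participants=n,
        n_variables_per_domain={d: 6 for d in syn.DOMAINS},
        true_log_hr={"medical_history_v1": b, "medical_history_v4": b},
        baseline_hazard_scale=0.004,
        censoring_rate=0.0,
        missing_rate=0.0,
        special_code_rate=0.0,
        domain_correlation=0.0,
        binary_prevalence=0.38,
        prs_log_hr=0.3,
        age_log_hr=0.0,
        sex_log_hr=0.0,
        seed=seed,
    )
    return syn.generate_cohort(cfg)


@pytest.fixture(scope="module")
def single_domain_models():
    cohort, catalog, truth = _effect_cohort()
    sig = sig_table(
        [
            ("medical_history_v1", "medical_history", 1.7),
            ("medical_history_v4", "medical_history", 1.7),
            ("lifestyle_v1", "lifestyle", 1.0),
            ("lifestyle_v4", "lifestyle", 1.0),
        ]
    )
    models = sc.build_domain_scores(sig, cohort, catalog)
    return cohort, models


class TestJointModel:
    def test_only_true_risk_domain_significant(self, single_domain_models):
        cohort, models = single_domain_models
        fit = sc.joint_domain_model(cohort, models)
        mh = fit["medical_history:unfavorable"]
        assert mh["hr"] > 1 and mh["p"] < 1e-4
        null = fit["lifestyle:unfavorable"]
        assert null["lo"] < 1 < null["hi"]

    def test_weighted_and_unweighted_sensitivity_same_direction(
        self, single_domain_models
    ):
        cohort, models = single_domain_models
        fw = sc.joint_domain_model(cohort, models, use_weighted=True)
        fu = sc.joint_domain_model(cohort, models, use_weighted=False)
        bw = fw["medical_history:unfavorable"]["beta"]
        bu = fu["medical_history:unfavorable"]["beta"]
        assert np.sign(bw) == np.sign(bu) == 1


class TestGxe:
    def test_reference_cell_is_one(self, single_domain_models):
        cohort, models = single_domain_models
        prs_groups = genetics.tertile_labels(cohort["prs"].to_numpy())
        grid, strat = sc.gxe_nine_groups(cohort, prs_groups, models["medical_history"])
        ref = grid[(grid["prs"] == "low") & (grid["category"] == "favorable")]
        assert ref["hr"].iloc[0] == 1.0 and bool(ref["reference"].iloc[0])
        assert len(grid) == 9
        # within-stratum table: unfavorable is the reference in each stratum
        for g in ("low", "medium", "high"):
            r = strat[(strat["prs"] == g) & (strat["category"] == "unfavorable")]
            assert r["hr"].iloc[0] == 1.0

    def test_multiplicative_null_grid(self, single_domain_models):
        """Without a true interaction, the 9-group HRs are consistent with
        the product of the marginal PRS and score effects."""
        cohort, models = single_domain_models
        prs_groups = genetics.tertile_labels(cohort["prs"].to_numpy())
        model = models["medical_history"]
        grid, _ = sc.gxe_nine_groups(cohort, prs_groups, model)
        # marginal fits
        data = cohort.copy()
        data["prs_high"] = (prs_groups == "high").astype(float)
        data["prs_med"] = (prs_groups == "medium").astype(float)
        data["unfav"] = (model.category == "unfavorable").astype(float)
        data["mod"] = (model.category == "moderate").astype(float)
        marg = sv.fit_cox(data, ["prs_high", "prs_med", "unfav", "mod"])
        expected = np.exp(
            marg["prs_high"]["beta"] + marg["unfav"]["beta"]
        )
        cell = grid[(grid["prs"] == "high") & (grid["category"] == "unfavorable")]
        lo, hi = cell["lo"].iloc[0], cell["hi"].iloc[0]
        assert lo < expected < hi

    def test_null_prs_rows_homogeneous(self):
        """With no true PRS effect, the same score tertile has similar HRs
        across PRS strata."""
        b = np.log(1.7)
        cfg = syn.GeneratorConfig(
            n_participants=20_000,
            n_variables_per_domain={d: 6 for d in syn.DOMAINS},
            true_log_hr={"medical_history_v1": b, "medical_history_v4": b},
            baseline_hazard_scale=0.004,
            censoring_rate=0.0, missing_rate=0.0, special_code_rate=0.0,
            domain_correlation=0.0, binary_prevalence=0.38,
            prs_log_hr=0.0, age_log_hr=0.0, sex_log_hr=0.0, seed=14,
        )
        cohort, catalog, _ = syn.generate_cohort(cfg)
        sig = sig_table(
            [
                ("medical_history_v1", "medical_history", 1.7),
                ("medical_history_v4", "medical_history", 1.7),
            ]
        )
        models = sc.build_domain_scores(sig, cohort, catalog)
        prs_groups = genetics.tertile_labels(cohort["prs"].to_numpy())
        grid, _ = sc.gxe_nine_groups(cohort, prs_groups, models["medical_history"])
        unfav = grid[grid["category"] == "unfavorable"].set_index("prs")
        for g in ("medium", "high"):
            # the confidence intervals of the three unfavorable cells overlap
            assert unfav.loc[g, "lo"] <= unfav.loc["low", "hi"]
            assert unfav.loc[g, "hi"] >= unfav.loc["low", "lo"]
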