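import numpy as np
import pandas as pd
import pytest

from estuaryuse.inference import (
    ModelScore,
    ModelSpec,
    aicc,
    build_design,
    durbin_watson,
    fit_model,
    group_summary,
    rank_models,
    screen_collinearity,
    weights_from_deltas,
)


def make_ar1_data(rng, phi=0.5, n_whales=4, T=60, beta_tide=0.4, sigma=0.3):
    rows = []
    for w in range(n_whales):
        tide = rng.standard_normal(T)
        e = np.empty(T)
        e[0] = rng.standard_normal() * sigma / np.sqrt(1 - phi**2)
        for t in range(1, T):
            e[t] = phi * e[t - 1] + rng.standard_normal() * sigma
        rows.append(
            pd.DataFrame(
                {"whale_id": f"W{w}", "tide": tide, "resp": np.exp(1.0 + beta_tide * tide + e)}
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestCollinearity:
    def test_duplicated_covariate_flagged(self, rng):
        x = rng.standard_normal(100)
        report = screen_collinearity(pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(100)}))
        assert any({"a", "b"} == {p[0], p[1]} for p in report["flagged_pairs"])
        assert "a" in report["flagged_vif"] and "b" in report["flagged_vif"]

    def test_orthogonal_design_vif_one(self):
        n = 8
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        report = screen_collinearity(pd.DataFrame({"a": a, "b": b}))
        assert report["vif"]["a"] == pytest.approx(1.0, abs=1e-10)
        assert report["vif"]["b"] == pytest.approx(1.0, abs=1e-10)

    def test_independent_covariates_rarely_flagged(self, rng):
        flags = 0
        for _ in range(40):
            X = pd.DataFrame(rng.standard_normal((500, 3)), columns=list("abc"))
            rep = screen_collinearity(X)
            flags += bool(rep["flagged_pairs"] or rep["flagged_vif"])
        assert flags <= 2  # ≥95% of null replicates unflagged

    def test_constant_covariate_infinite_vif(self, rng):
        X = pd.DataFrame({"a": np.ones(50), "b": rng.standard_normal(50)})
        rep = screen_collinearity(X)
        assert np.isinf(rep["vif"]["a"])
        assert "a" in rep["flagged_vif"]


class TestFitModel:
    def test_uncorrelated_fit_matches_statsmodels_ols(self, rng):
        import statsmodels.api as sm

        data = make_ar1_data(rng, phi=0.0).sort_values(["whale_id"]).reset_index(drop=True)
        spec = ModelSpec(response="resp", covariates=("tide",), correlation="none")
        fit = fit_model(data, spec)
        X = build_design(data, ("tide",), "whale_id")
        ols = sm.OLS(np.log(data["resp"]), X).fit()
        np.testing.assert_allclose(fit.params.to_numpy(), ols.params.to_numpy(), atol=1e-6)

    def test_phi_zero_reduces_to_uncorrelated_loglik(self, rng):
        data = make_ar1_data(rng)
        spec_ar = ModelSpec(response="resp", covariates=("tide",))
        spec_none = ModelSpec(response="resp", covariates=("tide",), correlation="none")
        fit_fixed = fit_model(data, spec_ar, fix_phi=0.0)
        fit_none = fit_model(data, spec_none)
        assert fit_fixed.loglik == pytest.approx(fit_none.loglik, abs=1e-8)
        np.testing.assert_allclose(
            fit_fixed.params.to_numpy(), fit_none.params.to_numpy(), atol=1e-12
        )

    def test_phi_estimate_near_truth(self, rng):
        data = make_ar1_data(rng, phi=0.6, T=300)
        fit = fit_model(data, ModelSpec(response="resp", covariates=("tide",)))
        assert fit.phi == pytest.approx(0.6, abs=0.1)

    def test_doubling_response_shifts_only_intercept(self, rng):
        data = make_ar1_data(rng)
        spec = ModelSpec(response="resp", covariates=("tide",))
        fit1 = fit_model(data, spec, fix_phi=0.3)
        data2 = data.assign(resp=data["resp"] * 2.0)
        fit2 = fit_model(data2, spec, fix_phi=0.3)
        diff = fit2.params - fit1.params
        assert diff["(Int)"] == pytest.approx(np.log(2.0), abs=1e-8)
        assert np.allclose(diff.drop("(Int)").to_numpy(), 0.0, atol=1e-8)

    def test_nonpositive_response_rejected(self, rng):
        data = make_ar1_data(rng)
        data.loc[0, "resp"] = 0.0
        with pytest.raises(ValueError):
            fit_model(data, ModelSpec(response="resp"))


class TestAicc:
    @pytest.mark.parametrize(
        "loglik,k,n,expected",
        [(-1682.236, 5, 1426, 3374.5), (-346.450, 7, 1426, 707.0)],
    )
    def test_published_model_table_values(self, loglik, k, n, expected):
        assert round(aicc(loglik, k, n), 1) == expected

    def test_k_zero_is_minus_twice_loglik(self):
        assert aicc(-10.0, 0, 50) == 20.0

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 5, 6)


class TestRanking:
    def test_published_weight_column(self):
        deltas = [0.00, 0.90, 1.86, 3.86, 14.21]
        w = weights_from_deltas(deltas)
        np.testing.assert_allclose(
            np.round(w, 3), [0.459, 0.293, 0.181, 0.067, 0.000], atol=1e-12
        )

    def test_published_top_weight_second_set(self):
        w = weights_from_deltas([0.00, 1.90, 22.33, 23.70, 43.25])
        assert round(float(w[0]), 3) == 0.721

    def test_single_model_weight_one(self):
        ranked = rank_models([ModelScore(name="only", k=2, loglik=-5.0, aicc=14.0)])
        assert ranked[0].weight == 1.0
        assert ranked[0].delta == 0.0

    def test_identical_aicc_weights_split(self):
        ranked = rank_models(
            [
                ModelScore(name="a", k=2, loglik=-5.0, aicc=14.0),
                ModelScore(name="b", k=2, loglik=-5.0, aicc=14.0),
            ]
        )
        assert [s.weight for s in ranked] == [0.5, 0.5]

    def test_weights_sum_to_one_and_sorted(self, rng):
        scores = [
            ModelScore(name=str(i), k=3, loglik=0.0, aicc=float(a))
            for i, a in enumerate(rng.uniform(100, 140, 8))
        ]
        ranked = rank_models(scores)
        assert sum(s.weight for s in ranked) == pytest.approx(1.0, abs=1e-9)
        assert all(a.aicc <= b.aicc for a, b in zip(ranked, ranked[1:]))
        assert ranked[0].delta == 0.0


class TestDurbinWatson:
    def test_white_noise_near_two(self, rng):
        e = rng.standard_normal(1000)
        assert 1.8 <= durbin_watson(e) <= 2.2

    def test_alternating_residuals_closed_form(self):
        n = 100
        e = np.tile([1.0, -1.0], n // 2)
        assert durbin_watson(e) == pytest.approx(4.0 * (n - 1) / n)

    def test_constant_residuals(self):
        assert durbin_watson(np.ones(10)) == 0.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            durbin_watson(np.zeros(10))

    def test_ar1_fit_constrains_autocorrelation(self, rng):
        # whitened residuals of the AR1 fit should look like white noise
        data = make_ar1_data(rng, phi=0.7, T=400, n_whales=2)
        fit = fit_model(data, ModelSpec(response="resp", covariates=("tide",)))
        raw_dw = durbin_watson(fit.residuals)
        e = fit.residuals
        whitened = e[1:] - fit.phi * e[:-1]
        white_dw = durbin_watson(whitened)
        assert raw_dw < 1.5  # raw residuals visibly autocorrelated
        assert 1.7 <= white_dw <= 2.3


class TestGroupSummary:
    def test_known_percentiles_linear_interpolation(self):
        vals = pd.Series(np.arange(1, 101, dtype=float))
        out = group_summary(vals, pd.Series(["g"] * 100))
        assert out.loc["g", "median"] == 50.5
        assert out.loc["g", "q25"] == 25.75
        assert out.loc["g", "q75"] == 75.25
        assert out.loc["g", "n"] == 100

    def test_single_value_group(self):
        out = group_summary(pd.Series([7.0]), pd.Series(["x"]))
        assert (out.loc["x", ["median", "q25", "q75"]] == 7.0).all()

    def test_scale_equivariance(self, rng):
        v = pd.Series(rng.uniform(1, 9, 40))
        g = pd.Series(["a"] * 40)
        base = group_summary(v, g)
        scaled = group_summary(v * 3.0, g)
        for col in ("median", "q25", "q75"):
            assert scaled.loc["a", col] == pytest.approx(3.0 * base.loc["a", col])
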