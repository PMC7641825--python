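import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from qolmap.dataset import MappingDataset
from qolmap.engines import (
    BOUNDARY_EPS,
    SECOND_LARGEST_INDEX,
    TARIFF_MIN,
    FittedDirectModel,
    IndirectModel,
    LinearPart,
    OrdinalItemModel,
    fit_direct,
    fit_ordinal_item,
    inverse_transform_index,
    item_level_probs,
    predict_expected_index,
    predict_indirect_index,
    simulate_index,
    squeeze_boundaries,
    transform_index,
)
from qolmap.valueset import DIMENSIONS


def _part(coefs: dict, covariates=None) -> LinearPart:
    covs = covariates if covariates is not None else [c for c in coefs if c != "intercept"]
    params = pd.Series({"intercept": coefs.get("intercept", 0.0),
                        **{c: coefs.get(c, 0.0) for c in covs}})
    return LinearPart(list(covs), params, pd.Series(np.nan, index=params.index))


def _random_indirect(seed, vs):
    rng = np.random.default_rng(seed)
    items = {}
    for d in DIMENSIONS:
        alphas = np.sort(rng.normal(0, 2, size=4))
        items[d] = OrdinalItemModel(
            item=d, alphas=alphas, covariates=["x1", "x2"],
            params=pd.Series(rng.normal(0, 0.5, 2), index=["x1", "x2"]),
            pvalues=pd.Series(np.nan, index=["x1", "x2"]),
        )
    return IndirectModel(items=items, valueset=vs)


class TestTransforms:
    def test_lower_anchor_maps_to_zero(self):
        assert transform_index(-0.025, "beta_full") == pytest.approx(0.0, abs=1e-15)
        assert transform_index(-0.025, "beta_twopart") == pytest.approx(0.0, abs=1e-15)

    def test_second_best_maps_to_one_in_twopart_mode(self):
        assert transform_index(0.895, "beta_twopart") == pytest.approx(1.0)

    def test_midpoint_of_full_range(self):
        assert transform_index(0.4875, "beta_full") == pytest.approx(0.5)

    def test_full_health_rejected_in_twopart_mode(self):
        with pytest.raises(ValueError, match="logistic part"):
            transform_index(1.0, "beta_twopart")

    def test_inverse_is_exact(self):
        y = np.linspace(-0.025, 0.895, 23)
        for mode in ("beta_full", "beta_twopart"):
            u = transform_index(y, mode)
            np.testing.assert_allclose(inverse_transform_index(u, mode), y, atol=1e-14)

    def test_boundary_squeeze(self):
        np.testing.assert_allclose(
            squeeze_boundaries(np.array([0.0, 1.0, 0.3])),
            [BOUNDARY_EPS, 1 - BOUNDARY_EPS, 0.3],
        )


class TestDirectExpectations:
    def test_certain_full_health_predicts_one(self):
        m = FittedDirectModel("twopart_beta", _part({"intercept": 0.0}),
                              logistic=_part({"intercept": 50.0}), aux={"phi": 8.0})
        assert predict_expected_index(m, {})[0] == pytest.approx(1.0)

    def test_beta_part_upper_bound_is_second_best_index(self):
        m = FittedDirectModel("twopart_beta", _part({"intercept": 50.0}),
                              logistic=_part({"intercept": -50.0}), aux={"phi": 8.0})
        assert predict_expected_index(m, {})[0] == pytest.approx(0.895, abs=1e-10)

    def test_two_part_mixture_arithmetic(self):
        # p = 0.5, mu = 0.5 -> 0.5*1 + 0.5*(-0.025 + 0.92*0.5) = 0.7175
        m = FittedDirectModel("twopart_beta", _part({"intercept": 0.0}),
                              logistic=_part({"intercept": 0.0}), aux={"phi": 8.0})
        assert predict_expected_index(m, {})[0] == pytest.approx(0.7175)

    def test_missing_covariate_named_in_error(self):
        m = FittedDirectModel("linear", _part({"intercept": 0.0, "pf": 0.01}))
        with pytest.raises(KeyError, match="pf"):
            predict_expected_index(m, pd.DataFrame({"rf": [50.0]}))


class TestDirectFitting:
    def test_linear_consistency(self, eortc_twopart_cohort):
        rng = np.random.default_rng(3)
        df = eortc_twopart_cohort.df.copy()
        truth = {"intercept": 0.3, "pf": 0.004, "pa": -0.002}
        df["y"] = (truth["intercept"] + truth["pf"] * df.pf + truth["pa"] * df.pa
                   + rng.normal(0, 0.1, len(df)))
        m = fit_direct("linear", MappingDataset(df, "eortc"), ["pf", "pa"])
        for k, v in truth.items():
            assert abs(m.part.params[k] - v) < 3 * m.part.bse[k]
        # mean training residual vanishes by the normal equations
        resid = df["y"].to_numpy() - predict_expected_index(m, df)
        assert abs(resid.mean()) < 1e-8

    def test_beta_recovery(self, eortc_twopart_cohort):
        rng = np.random.default_rng(4)
        df = eortc_twopart_cohort.df.copy()
        mu = expit(-1.0 + 0.02 * df.pf)
        u = rng.beta(mu * 8.0, (1 - mu) * 8.0)
        df["y"] = inverse_transform_index(u, "beta_full")
        m = fit_direct("beta", MappingDataset(df, "eortc"), ["pf"])
        assert abs(m.part.params["pf"] - 0.02) < 3 * m.part.bse["pf"]
        assert m.aux["phi"] == pytest.approx(8.0, rel=0.15)

    def test_tobit_recovery(self, eortc_twopart_cohort):
        rng = np.random.default_rng(5)
        df = eortc_twopart_cohort.df.copy()
        latent = 0.5 + 0.005 * df.pf + rng.normal(0, 0.15, len(df))
        df["y"] = np.clip(latent, TARIFF_MIN, 1.0)
        m = fit_direct("tobit", MappingDataset(df, "eortc"), ["pf"])
        assert abs(m.part.params["pf"] - 0.005) < 3 * m.part.bse["pf"]
        assert m.aux["sigma"] == pytest.approx(0.15, rel=0.1)
        pred = predict_expected_index(m, df)
        assert (pred >= TARIFF_MIN - 1e-9).all() and (pred <= 1 + 1e-9).all()

    def test_tweedie_mean_model_consistency(self, eortc_twopart_cohort):
        # quasi-likelihood estimates the log-link mean consistently even
        # though the simulated disutility is zero-inflated gamma
        rng = np.random.default_rng(6)
        df = eortc_twopart_cohort.df.copy()
        mu = np.exp(-1.0 - 0.02 * (df.pf - 70))
        zero = rng.random(len(df)) < 0.2
        d = np.where(zero, 0.0, rng.gamma(2.0, mu / (2.0 * 0.8)))
        df["y"] = 1.0 - d
        m = fit_direct("tweedie", MappingDataset(df, "eortc"), ["pf"],
                       tweedie_power=1.5)
        assert m.aux["power"] == 1.5
        assert abs(m.part.params["pf"] - (-0.02)) < 3 * m.part.bse["pf"]
        assert (predict_expected_index(m, df) < 1.0).all()

    def test_tweedie_power_profile_stays_in_grid(self, eortc_twopart_cohort):
        m = fit_direct("tweedie", eortc_twopart_cohort, ["pf", "ghs"])
        assert 1.0 < m.aux["power"] < 2.0

    def test_twopart_beta_recovery_from_generating_truth(self, eortc_twopart_cohort):
        from qolmap.synthcohort import truth_report

        truth = truth_report(eortc_twopart_cohort)["direct"]
        m = fit_direct("twopart_beta", eortc_twopart_cohort,
                       truth["part"]["covariates"],
                       logistic_covariates=truth["logistic"]["covariates"])
        for c, v in truth["part"]["params"].items():
            assert abs(m.part.params[c] - v) < 4 * m.part.bse[c]
        pred = predict_expected_index(m, eortc_twopart_cohort.df)
        assert (pred > TARIFF_MIN).all() and (pred <= 1.0 + 1e-12).all()

    def test_twopart_needs_both_classes(self, eortc_twopart_cohort):
        df = eortc_twopart_cohort.df.copy()
        df["y"] = df["y"].clip(upper=0.9)  # no full-health rows
        with pytest.raises(ValueError, match="full-health"):
            fit_direct("twopart_beta", MappingDataset(df, "eortc"), ["pf"])
        df["y"] = 1.0
        with pytest.raises(ValueError, match="non-full-health"):
            fit_direct("twopart_beta", MappingDataset(df, "eortc"), ["pf"])

    def test_twopart_linear_continuous_residual_mean_zero(self, eortc_twopart_cohort):
        m = fit_direct("twopart_linear", eortc_twopart_cohort, ["pf", "ghs"])
        df = eortc_twopart_cohort.df
        rest = df[df["y"] < 1 - 1e-12]
        resid = rest["y"].to_numpy() - m.part.linpred(rest)
        assert abs(resid.mean()) < 1e-8

    def test_unknown_method_rejected(self, eortc_twopart_cohort):
        with pytest.raises(ValueError, match="unknown direct method"):
            fit_direct("mixture", eortc_twopart_cohort, ["pf"])


class TestOrdinal:
    def test_equal_thresholds_collapse_middle_mass(self):
        m = OrdinalItemModel("mo", np.zeros(4), [], pd.Series(dtype=float),
                             pd.Series(dtype=float))
        probs = item_level_probs(m, pd.DataFrame(index=[0]))
        np.testing.assert_allclose(probs[0], [0.5, 0, 0, 0, 0.5], atol=1e-12)

    def test_very_negative_thresholds_put_mass_on_level5(self):
        m = OrdinalItemModel("mo", np.full(4, -40.0), [], pd.Series(dtype=float),
                             pd.Series(dtype=float))
        probs = item_level_probs(m, pd.DataFrame(index=[0]))
        np.testing.assert_allclose(probs[0], [0, 0, 0, 0, 1], atol=1e-12)

    def test_probs_match_cumulative_logit_oracle(self):
        rng = np.random.default_rng(8)
        alphas = np.sort(rng.normal(0, 2, 4))
        beta = rng.normal(0, 0.5, 2)
        m = OrdinalItemModel("pd", alphas, ["x1", "x2"],
                             pd.Series(beta, index=["x1", "x2"]),
                             pd.Series(np.nan, index=["x1", "x2"]))
        x = pd.DataFrame({"x1": rng.normal(size=20), "x2": rng.normal(size=20)})
        probs = item_level_probs(m, x)
        for i in range(len(x)):
            xb = beta[0] * x.x1[i] + beta[1] * x.x2[i]
            cum = [0.0] + [1 / (1 + np.exp(-(a + xb))) for a in alphas] + [1.0]
            oracle = np.diff(cum)
            np.testing.assert_allclose(probs[i], oracle, atol=1e-10)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ValueError, match="non-decreasing"):
            OrdinalItemModel("mo", np.array([1.0, 0.5, 2.0, 3.0]), [],
                             pd.Series(dtype=float), pd.Series(dtype=float))

    def test_interceptish_fit_recovers_logit_of_cumulative_frequencies(
            self, eortc_cohort):
        rng = np.random.default_rng(9)
        df = eortc_cohort.df.copy()
        n = len(df)
        df["mo"] = rng.choice([1, 2, 3, 4, 5], size=n)  # equal frequencies
        df["noise"] = rng.normal(size=n)
        m = fit_ordinal_item(MappingDataset(df, "eortc"), "mo", ["noise"])
        freq = np.array([(df["mo"] <= j).mean() for j in range(1, 5)])
        np.testing.assert_allclose(m.alphas, logit(freq), atol=0.1)

    def test_single_category_rejected(self, eortc_cohort):
        df = eortc_cohort.df.copy()
        df["mo"] = 1
        with pytest.raises(ValueError, match="single observed category"):
            fit_ordinal_item(MappingDataset(df, "eortc"), "mo", ["pf"])

    def test_parameterization_sign_convention(self, eortc_cohort):
        """A covariate generated to favour good levels must come back
        with a positive coefficient under the adopted convention."""
        rng = np.random.default_rng(10)
        df = eortc_cohort.df.copy()
        x = rng.normal(size=len(df))
        cum = expit(np.array([-1.5, -0.5, 0.5, 1.5])[None, :] + (1.2 * x)[:, None])
        cum = np.c_[np.zeros(len(df)), cum, np.ones(len(df))]
        u = rng.random(len(df))
        df["mo"] = 1 + (u[:, None] > cum[:, 1:-1]).sum(axis=1)
        df["xcov"] = x
        m = fit_ordinal_item(MappingDataset(df, "eortc"), "mo", ["xcov"])
        assert abs(m.params["xcov"] - 1.2) < 3 * m.bse["xcov"]


class TestIndirectExpectation:
    def test_degenerate_models_hit_tariff_anchors(self, tariff):
        for target_level, expected in ((1, 1.0), (5, -0.025)):
            sign = 1.0 if target_level == 1 else -1.0
            items = {
                d: OrdinalItemModel(d, np.sort(np.full(4, sign * 40.0)), [],
                                    pd.Series(dtype=float), pd.Series(dtype=float))
                for d in DIMENSIONS
            }
            m = IndirectModel(items=items, valueset=tariff)
            got = predict_indirect_index(m, pd.DataFrame(index=[0]))[0]
            assert got == pytest.approx(expected, abs=1e-10)

    def test_equals_exhaustive_enumeration(self, tariff):
        m = _random_indirect(11, tariff)
        rng = np.random.default_rng(12)
        x = pd.DataFrame({"x1": rng.normal(size=5), "x2": rng.normal(size=5)})
        fast = predict_indirect_index(m, x)
        probs = {d: item_level_probs(m.items[d], x) for d in DIMENSIONS}
        for i in range(len(x)):
            total = 0.0
            for state in itertools.product(range(1, 6), repeat=5):
                p = np.prod([probs[d][i, l - 1] for d, l in zip(DIMENSIONS, state)])
                idx = 1.0 - sum(
                    tariff.decrements[j, l - 1] for j, l in enumerate(state)
                )
                total += p * idx
            assert abs(fast[i] - total) < 1e-12

    def test_missing_item_model_rejected(self, tariff):
        m = _random_indirect(13, tariff)
        items = dict(m.items)
        items.pop("pd")
        with pytest.raises(ValueError, match="pd"):
            IndirectModel(items=items, valueset=tariff)


class TestSimulation:
    def test_certain_full_health_draws_ones(self):
        m = FittedDirectModel("twopart_beta", _part({"intercept": 0.0}),
                              logistic=_part({"intercept": 50.0}), aux={"phi": 8.0})
        draws = simulate_index(m, pd.DataFrame(index=range(200)), seed=1)
        assert (draws == 1.0).all()

    @pytest.mark.parametrize("method", ["linear", "beta", "tobit",
                                        "twopart_linear", "twopart_beta"])
    def test_large_sample_mean_matches_expectation(self, method,
                                                   eortc_twopart_cohort):
        covs = ["pf", "ghs"]
        m = fit_direct(method, eortc_twopart_cohort, covs)
        row = eortc_twopart_cohort.df.iloc[[0]][covs]
        big = row.loc[row.index.repeat(40000)].reset_index(drop=True)
        draws = simulate_index(m, big, seed=2)
        expect = predict_expected_index(m, row)[0]
        assert draws.mean() == pytest.approx(expect, abs=0.004)

    def test_indirect_draws_only_attainable_values(self, tariff):
        m = _random_indirect(14, tariff)
        rng = np.random.default_rng(15)
        x = pd.DataFrame({"x1": rng.normal(size=500), "x2": rng.normal(size=500)})
        draws, levels = simulate_index(m, x, seed=3)
        attainable = np.unique(np.round(tariff.enumerate_indexes(), 9))
        assert np.isin(np.round(draws, 9), attainable).all()
        assert levels.min() >= 1 and levels.max() <= 5

    def test_reproducible_given_seed(self, eortc_twopart_cohort):
        m = fit_direct("twopart_beta", eortc_twopart_cohort, ["pf", "ghs"])
        x = eortc_twopart_cohort.df.iloc[:50]
        d1 = simulate_index(m, x, seed=7)
        d2 = simulate_index(m, x, seed=7)
        np.testing.assert_array_equal(d1, d2)

    def test_tweedie_has_no_generative_law(self, eortc_twopart_cohort):
        m = fit_direct("tweedie", eortc_twopart_cohort, ["pf"], tweedie_power=1.5)
        with pytest.raises(ValueError, match="generative"):
            simulate_index(m, eortc_twopart_cohort.df.iloc[:5], seed=0)
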