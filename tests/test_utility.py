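import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wormchoice.core import BudgetSpec
from wormchoice.garp import check_garp
from wormchoice.synth import default_worm_ensemble, simulate_ces_chooser
from wormchoice.utility import (
    CESParams,
    CESTobitModel,
    LinearUtilityParams,
    alternative_maximand_predictions,
    ces_optimal_share,
    ces_utility,
    cobb_douglas_utility,
    linear_utility,
    predict_ensemble_choices,
)

from _oracles import grid_max_utility_share


class TestLinearUtility:
    def test_examples(self):
        assert linear_utility(1, 0, beta=10 / 11) == pytest.approx(10 / 11)
        assert linear_utility(2, 2, beta=0.5) == pytest.approx(2.0)
        assert linear_utility(0, 0, beta=0.3) == 0.0

    def test_out_of_range_beta_rejected(self):
        with pytest.raises(ValueError):
            linear_utility(1, 1, beta=1.2)

    def test_exchange_rate(self):
        assert LinearUtilityParams(10 / 11).exchange_rate == pytest.approx(10.0)


class TestCESUtility:
    def test_rho_one_equals_linear(self, rng):
        q = rng.uniform(0, 5, size=(1000, 2))
        beta = 0.37
        got = ces_utility(q[:, 0], q[:, 1], CESParams(beta, 1.0))
        want = linear_utility(q[:, 0], q[:, 1], beta)
        np.testing.assert_allclose(got, want, rtol=1e-12)

    def test_equal_quantities_identity(self, rng):
        # U(c, c) = c for any (beta, rho): degree-one homogeneity anchor
        for _ in range(50):
            c = rng.uniform(0.01, 10)
            params = CESParams(rng.uniform(0.05, 0.95), rng.choice([-2.0, -0.3, 0.4, 1.0]))
            assert ces_utility(c, c, params) == pytest.approx(c, rel=1e-10)

    @settings(max_examples=200, deadline=None)
    @given(
        qh=st.floats(0.01, 100),
        qm=st.floats(0.01, 100),
        c=st.floats(0.01, 100),
        beta=st.floats(0.05, 0.95),
        rho=st.floats(-3, 1).filter(lambda r: abs(r) > 1e-3),
    )
    def test_homogeneous_degree_one(self, qh, qm, c, beta, rho):
        params = CESParams(beta, rho)
        assert ces_utility(c * qh, c * qm, params) == pytest.approx(
            c * ces_utility(qh, qm, params), rel=1e-9
        )

    def test_cobb_douglas_is_the_rho_to_zero_limit(self):
        qh, qm, beta = 2.0, 5.0, 0.3
        target = cobb_douglas_utility(qh, qm, beta)
        for rho in (1e-3, -1e-3, 1e-5, -1e-5):
            got = ces_utility(qh, qm, CESParams(beta, rho))
            assert got == pytest.approx(target, rel=1e-2 * abs(rho) / 1e-3 + 1e-6)

    def test_zero_quantity_with_negative_rho_is_zero(self):
        assert ces_utility(0.0, 3.0, CESParams(0.5, -1.0)) == 0.0
        assert ces_utility(np.array([0.0, 1.0]), np.array([2.0, 2.0]),
                           CESParams(0.5, -0.5))[0] == 0.0

    def test_rho_zero_rejected(self):
        with pytest.raises(ValueError):
            CESParams(0.5, 0.0)


class TestCESOptimalShare:
    def test_symmetric_indifference(self):
        assert ces_optimal_share(CESParams(0.5, 0.5), 1.0, 1.0) == pytest.approx(0.5)

    def test_share_maximizes_utility_on_budget_line(self, rng):
        """The closed-form share beats a dense grid search on the budget line."""
        for _ in range(100):
            params = CESParams(rng.uniform(0.1, 0.9), rng.uniform(-2.0, 0.9))
            d_H, d_M = 10 ** rng.uniform(-1, 1, size=2)
            s = ces_optimal_share(params, 1 / d_H, 1 / d_M)
            util = lambda qh, qm: ces_utility(qh, qm, params)
            s_grid, u_grid = grid_max_utility_share(util, d_H, d_M)
            u_closed = util(s * d_H, (1 - s) * d_M)
            assert u_closed >= u_grid - 1e-9
            assert s == pytest.approx(s_grid, abs=2e-4)

    def test_beta_to_one_limit(self):
        assert ces_optimal_share(CESParams(0.999, 0.5), 1.0, 1.0) > 0.99

    def test_monotone_in_beta_and_density_ratio(self):
        betas = np.linspace(0.05, 0.95, 19)
        shares = [ces_optimal_share(CESParams(b, 0.4), 1.0, 1.0) for b in betas]
        assert (np.diff(shares) > 0).all()
        ratios = 10 ** np.linspace(-1, 1, 21)
        shares = [
            ces_optimal_share(CESParams(0.4, 0.4), 1.0 / d, 1.0) for d in ratios
        ]  # d_H rising, p_H falling
        assert (np.diff(shares) > 0).all()

    def test_perfect_substitutes_corner_with_warning(self):
        with pytest.warns(UserWarning):
            s = ces_optimal_share(CESParams(0.9, 1.0), 1.0, 1.0)
        assert s == 1.0
        with pytest.warns(UserWarning):
            s = ces_optimal_share(CESParams(0.1, 1.0), 1.0, 1.0)
        assert s == 0.0
        with pytest.warns(UserWarning):
            s = ces_optimal_share(CESParams(0.5, 1.0), 1.0, 1.0)
        assert s == 0.5


class TestCESTobit:
    def test_noiseless_recovery(self):
        ens = default_worm_ensemble()
        table = simulate_ces_chooser(
            CESParams(0.7, 0.4), sigma=0.0, ensemble=ens, n_worms=5, seed=1
        )
        fit = CESTobitModel.from_dataframe(table).fit()
        assert fit.beta == pytest.approx(0.7, abs=0.01)
        assert fit.rho == pytest.approx(0.4, abs=0.05)

    def test_symmetric_shares_give_half_beta(self):
        budgets = [BudgetSpec(str(i), d, d) for i, d in enumerate((0.5, 1.0, 2.0))]
        obs = [(b, 0.5) for b in budgets for _ in range(10)]
        fit = CESTobitModel.from_observations(obs).fit()
        assert fit.beta == pytest.approx(0.5, abs=0.02)

    def test_linear_chooser_pushes_rho_to_upper_bound(self, rng):
        # corner choices with small noise: curvature estimate near rho = 1
        ens = default_worm_ensemble()
        corner = [1.0 if 0.9 * b.d_H > 0.1 * b.d_M else 0.0 for b in ens]
        shares = np.clip(
            np.repeat(corner, 15) + rng.normal(0, 0.03, 15 * len(ens)), 0, 1
        )
        prices = np.repeat([[b.p_H, b.p_M] for b in ens], 15, axis=0)
        fit = CESTobitModel(shares, prices).fit()
        assert fit.rho > 0.9

    def test_loglik_peaks_at_truth_on_large_sample(self):
        ens = default_worm_ensemble()
        table = simulate_ces_chooser(
            CESParams(0.6, 0.3), sigma=0.08, ensemble=ens, n_worms=300, seed=7
        )
        model = CESTobitModel.from_dataframe(table)
        ll_true = model.loglike([0.6, 0.3, 0.08])
        for perturbed in ([0.7, 0.3, 0.08], [0.6, -0.5, 0.08], [0.6, 0.3, 0.2]):
            assert ll_true > model.loglike(perturbed)

    def test_all_censored_rejected(self):
        prices = np.array([[1.0, 1.0], [2.0, 0.5], [0.5, 2.0]])
        with pytest.raises(ValueError):
            CESTobitModel(np.array([0.0, 1.0, 1.0]), prices)

    def test_summary_mentions_parameters(self):
        ens = default_worm_ensemble()
        table = simulate_ces_chooser(
            CESParams(0.7, 0.4), sigma=0.05, ensemble=ens, n_worms=10, seed=2
        )
        fit = CESTobitModel.from_dataframe(table).fit()
        text = fit.summary()
        assert "beta" in text and "rho" in text and "tobit" in text


class TestEnsemblePredictions:
    def test_symmetric_params_split_equal_densities(self):
        ens = [BudgetSpec("e", 2.0, 2.0)]
        data = predict_ensemble_choices(CESParams(0.5, 0.5), ens)
        np.testing.assert_allclose(data.bundles[0], [1.0, 1.0])

    def test_predictions_lie_on_budget_lines_and_pass_garp(self, rng):
        for _ in range(50):
            params = CESParams(rng.uniform(0.2, 0.8), rng.uniform(-1.5, 0.9))
            ratios = np.sort(rng.uniform(-1.5, 1.5, size=6))
            ens = [
                BudgetSpec(f"b{i}", 10 ** (r / 2), 10 ** (-r / 2))
                for i, r in enumerate(ratios)
            ]
            data = predict_ensemble_choices(params, ens)
            np.testing.assert_allclose(data.expenditures, 1.0, rtol=1e-9)
            assert check_garp(data).passes

    def test_tangency_beats_random_feasible_bundles(self, rng):
        params = CESParams(0.65, 0.35)
        ens = default_worm_ensemble()
        data = predict_ensemble_choices(params, ens)
        for b, bundle in zip(ens, data.bundles):
            u_star = ces_utility(bundle[0], bundle[1], params)
            f = rng.uniform(0, 1, size=1000)
            scale = rng.uniform(0, 1, size=1000)  # interior of the budget set
            u_rand = ces_utility(scale * f * b.d_H, scale * (1 - f) * b.d_M, params)
            assert (u_star >= u_rand - 1e-12).all()


class TestAlternativeMaximands:
    def test_growth_potential_prefers_h_at_equal_density(self):
        ens = [BudgetSpec("e", 1.0, 1.0)]
        preds = alternative_maximand_predictions(ens, 0.50, 0.43)
        assert preds["growth_potential"][0] == 1.0
        assert preds["total_food"][0] == 0.5
        assert preds["h_only"][0] == 1.0

    def test_total_food_follows_denser_stream(self):
        ens = [BudgetSpec("x", 0.1, 3.0), BudgetSpec("y", 3.0, 0.1)]
        preds = alternative_maximand_predictions(ens)
        np.testing.assert_allclose(preds["total_food"], [0.0, 1.0])

    def test_corner_solutions_off_equality_locus(self, rng):
        ens = [
            BudgetSpec(f"b{i}", 10 ** rng.uniform(-1, 1), 10 ** rng.uniform(-1, 1))
            for i in range(30)
        ]
        preds = alternative_maximand_predictions(ens)
        for name in ("total_food", "growth_potential"):
            off_locus = [
                s
                for b, s in zip(ens, preds[name])
                if not np.isclose(b.d_H, b.d_M)
                and not np.isclose(0.50 * b.d_H, 0.43 * b.d_M)
            ]
            assert set(np.unique(off_locus)) <= {0.0, 1.0}

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            alternative_maximand_predictions([BudgetSpec("e", 1, 1)], 0.0, 0.4)
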