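import itertools
import json

import numpy as np
import pandas as pd
import pytest

from wormchoice.core import BudgetSpec
from wormchoice.curves import fit_price_ratio_sigmoid, sigmoid
from wormchoice.garp import PriceQuantityDataset, check_garp
from wormchoice.io import read_choice_table, summarize_choices
from wormchoice.synth import (
    GeneratorSpec,
    default_worm_ensemble,
    generate_ensemble,
    simulate_ces_chooser,
    simulate_choices,
    write_fixtures,
)
from wormchoice.utility import CESParams, CESTobitModel


class TestGenerateEnsemble:
    def test_zero_ratio_gives_equal_anchor_densities(self):
        (b,) = generate_ensemble([0.0], anchor_density=1.0)
        assert b.d_H == pytest.approx(1.0) and b.d_M == pytest.approx(1.0)

    def test_unit_ratio_splits_geometrically(self):
        (b,) = generate_ensemble([1.0], anchor_density=1.0)
        assert b.d_H == pytest.approx(10**0.5)
        assert b.d_M == pytest.approx(10**-0.5)

    def test_constraints_hold_for_random_ratios(self, rng):
        ratios = rng.uniform(-2, 2, size=20)
        for anchor in (0.5, 1.0, 2.0):
            ens = generate_ensemble(ratios, anchor)
            for b, r in zip(ens, ratios):
                assert b.d_H * b.d_M == pytest.approx(anchor**2, rel=1e-10)
                assert b.r == pytest.approx(r, abs=1e-10)

    def test_sorted_ratios_give_distinct_pairwise_intersections(self, rng):
        """Budget lines from distinct ratios cross at pairwise distinct points."""
        ratios = np.sort(rng.uniform(-1.5, 1.5, size=8))
        ens = generate_ensemble(ratios)
        points = []
        for a, b in itertools.combinations(ens, 2):
            # line: x/d_H + y/d_M = 1; solve the 2x2 system
            A = np.array([[1 / a.d_H, 1 / a.d_M], [1 / b.d_H, 1 / b.d_M]])
            xy = np.linalg.solve(A, np.ones(2))
            points.append(tuple(np.round(xy, 9)))
        assert len(set(points)) == len(points)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            generate_ensemble([np.inf])
        with pytest.raises(ValueError):
            generate_ensemble([0.0], anchor_density=0.0)


class TestSimulateChoices:
    def test_zero_dispersion_round_trip_recovers_sigmoid(self):
        spec = GeneratorSpec(
            ensemble=tuple(default_worm_ensemble()),
            r0=-0.3, k=0.5, dispersion=0.0,
            pumps_model="constant", pumps_mean=100_000,
            n_worms_per_budget=3, seed=0,
        )
        table = simulate_choices(spec)
        summary = summarize_choices(table)
        fit = fit_price_ratio_sigmoid(summary["r"], summary["mean_fH"])
        assert fit.r0 == pytest.approx(-0.3, abs=1e-4)
        assert fit.k == pytest.approx(0.5, abs=1e-4)

    def test_same_seed_identical_table(self):
        spec = GeneratorSpec(ensemble=tuple(default_worm_ensemble()), seed=123)
        pd.testing.assert_frame_equal(simulate_choices(spec), simulate_choices(spec))

    def test_counts_and_shares_well_formed(self, rng):
        spec = GeneratorSpec(
            ensemble=tuple(default_worm_ensemble()),
            dispersion=0.2, n_worms_per_budget=20, seed=9,
        )
        table = simulate_choices(spec)
        assert (table["n_H"] >= 0).all() and (table["n_M"] >= 0).all()
        N = table["n_H"] + table["n_M"]
        assert (N >= 1).all()
        f = table["n_H"] / N
        assert ((f >= 0) & (f <= 1)).all()
        assert len(table) == 7 * 20

    def test_dwell_times_express_preference_at_equal_frequency(self):
        spec = GeneratorSpec(
            ensemble=tuple(default_worm_ensemble()),
            with_dwell_times=True, pump_rate_hz=4.0, seed=5,
        )
        table = simulate_choices(spec)
        both = table[(table["n_H"] > 0) & (table["n_M"] > 0)]
        f_dwell = both["t_H"] / (both["t_H"] + both["t_M"])
        f_pumps = both["n_H"] / (both["n_H"] + both["n_M"])
        np.testing.assert_allclose(f_dwell, f_pumps, rtol=1e-12)
        np.testing.assert_allclose(both["n_H"] / both["t_H"], 4.0)

    def test_mean_share_converges_to_sigmoid(self):
        """Law of large numbers: the empirical mean approaches the curve."""
        ens = generate_ensemble([-0.5, 0.0, 0.5])
        sd = 0.1
        n = 10_000
        spec = GeneratorSpec(
            ensemble=tuple(ens), r0=-0.2, k=0.6, dispersion=sd,
            n_worms_per_budget=n, seed=21,
        )
        summary = summarize_choices(simulate_choices(spec))
        from scipy import stats

        for _, row in summary.iterrows():
            m = sigmoid(row["r"], -0.2, 0.6)
            # the generator draws from the truncated normal, whose mean is
            # shifted from the sigmoid value near the bounds
            target = stats.truncnorm.mean((0 - m) / sd, (1 - m) / sd, loc=m, scale=sd)
            assert abs(row["mean_fH"] - target) < 3 * sd / np.sqrt(n) + 1e-3

    def test_beta_noise_model_and_bad_params(self):
        spec = GeneratorSpec(
            ensemble=tuple(default_worm_ensemble()),
            noise_model="beta", dispersion=0.15, seed=2,
        )
        table = simulate_choices(spec)
        f = table["n_H"] / (table["n_H"] + table["n_M"])
        assert ((f >= 0) & (f <= 1)).all()
        with pytest.raises(ValueError):
            GeneratorSpec(ensemble=tuple(default_worm_ensemble()), noise_model="bogus")
        with pytest.raises(ValueError):
            GeneratorSpec(ensemble=(), seed=0)

    def test_pipeline_round_trip_passes_garp(self):
        """Sigmoid-mean data yield violation-free mean choices (monotone curve
        plus modest noise), across many seeded runs."""
        ens = default_worm_ensemble()
        passes = 0
        n_runs = 100
        for seed in range(n_runs):
            spec = GeneratorSpec(
                ensemble=tuple(ens), r0=-0.3, k=0.5, dispersion=0.1,
                n_worms_per_budget=20, seed=seed,
            )
            summary = summarize_choices(simulate_choices(spec))
            data = PriceQuantityDataset.from_mean_shares(
                ens, summary.sort_values("r")["mean_fH"]
            )
            passes += check_garp(data, compute_ccei=False).passes
        assert passes / n_runs >= 0.99


class TestSimulateCESChooser:
    def test_zero_sigma_recovery(self):
        ens = default_worm_ensemble()
        table = simulate_ces_chooser(CESParams(0.6, 0.3), 0.0, ens, 4, seed=0)
        fit = CESTobitModel.from_dataframe(table).fit()
        assert fit.beta == pytest.approx(0.6, abs=0.01)
        assert fit.rho == pytest.approx(0.3, abs=0.05)

    def test_symmetric_chooser_indifferent_at_equal_price(self):
        ens = [BudgetSpec("e", 1.0, 1.0)]
        table = simulate_ces_chooser(CESParams(0.5, 0.5), 0.0, ens, 10, seed=1)
        f = table["n_H"] / (table["n_H"] + table["n_M"])
        np.testing.assert_allclose(f, 0.5)


class TestWriteFixtures:
    def test_round_trip_and_manifest(self, tmp_path):
        spec = GeneratorSpec(
            ensemble=tuple(default_worm_ensemble()), n_worms_per_budget=5, seed=77
        )
        table = simulate_choices(spec)
        paths = write_fixtures({"choices": table}, str(tmp_path), spec=spec)
        csv_path = [p for p in paths if p.endswith(".csv")][0]
        back = read_choice_table(csv_path)
        pd.testing.assert_frame_equal(
            back[["group", "budget_id", "worm_id", "n_H", "n_M"]],
            table[["group", "budget_id", "worm_id", "n_H", "n_M"]],
        )
        with open([p for p in paths if p.endswith("manifest.json")][0]) as fh:
            manifest = json.load(fh)
        assert manifest["generator"]["seed"] == 77
        assert manifest["files"] == ["choices.csv"]
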