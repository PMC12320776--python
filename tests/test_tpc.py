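"""TPC fitting, AICc selection, derived parameters, bootstrap, contrasts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from sharkescape import simulate as sim
from sharkescape import tpc


SIGMA_FROM_330 = tpc.sigma_from_breadth(3.30)


def gaussian_data(temps=(26, 27, 28, 29, 30, 31, 32), a=317.10, t_opt=29.15,
                  sigma=SIGMA_FROM_330):
    t = np.asarray(temps, dtype=float)
    return t, tpc.gaussian_curve(t, a, t_opt, sigma)


class TestFitModel:
    def test_noiseless_gaussian_round_trip(self):
        t, y = gaussian_data()
        model = tpc.fit_model((t, y), shape="gaussian", seed=0)
        assert model.params["a"] == pytest.approx(317.10, rel=1e-6)
        assert model.params["t_opt"] == pytest.approx(29.15, rel=1e-6)
        assert model.params["sigma"] == pytest.approx(SIGMA_FROM_330, rel=1e-6)

    def test_exact_parabola_has_zero_rss(self):
        t = np.array([25.0, 27.0, 28.0, 29.0, 31.0, 33.0])
        y = -2.0 * t**2 + 120.0 * t - 1500.0
        model = tpc.fit_model((t, y), shape="quadratic", seed=0)
        assert model.rss == pytest.approx(0.0, abs=1e-12 * np.abs(y).max() ** 2 + 1e-8)

    def test_three_temperature_design_warns_but_fits(self):
        data = sim.gen_aas_dataset(seed=0)
        with pytest.warns(UserWarning, match="three"):
            model = tpc.fit_model(data, shape="gaussian", seed=0)
        assert 27.0 <= model.params["t_opt"] <= 31.0

    def test_deterministic_per_seed(self):
        data = sim.gen_aas_dataset(seed=5)
        with pytest.warns(UserWarning):
            m1 = tpc.fit_model(data, seed=11)
            m2 = tpc.fit_model(data, seed=11)
        assert m1.params == m2.params

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            tpc.fit_model((np.array([27.0, 27.0]), np.array([1.0, 2.0])))


class TestEstimatorInterface:
    def test_fit_predict_and_params(self):
        t, y = gaussian_data()
        est = tpc.ThermalPerformanceCurve(random_state=0).fit(t[:, None], y)
        np.testing.assert_allclose(est.predict(t[:, None]), y, rtol=1e-5)
        assert est.aicc_ == est.model_.aicc
        # sklearn param protocol round-trips
        clone_params = est.get_params()
        assert clone_params["n_starts"] == 64
        d = est.derived()
        assert d.t_peak == pytest.approx(29.15, rel=1e-6)


class TestAICc:
    def test_delta_formula_for_equal_k(self):
        # RSS 100 vs 200 at n=25 with 3+1 parameters each: delta = 25 ln 2
        delta = tpc.aicc(25, 200.0, 3) - tpc.aicc(25, 100.0, 3)
        assert delta == pytest.approx(25 * np.log(2.0))

    def test_tie_goes_to_first_listed(self):
        m1 = tpc.TPCModel("gaussian", {}, 25, 100.0, tpc.aicc(25, 100.0, 3))
        m2 = tpc.TPCModel("quadratic", {}, 25, 100.0, tpc.aicc(25, 100.0, 3))
        best, table = tpc.aicc_select([m1, m2])
        assert best is m1
        assert table["delta_aicc"].tolist() == [0.0, 0.0]

    def test_undefined_for_tiny_n(self):
        with pytest.raises(ValueError):
            tpc.aicc(5, 10.0, 3)

    def test_mismatched_data_rejected(self):
        m1 = tpc.TPCModel("gaussian", {}, 25, 100.0, 0.0)
        m2 = tpc.TPCModel("quadratic", {}, 24, 100.0, 0.0)
        with pytest.raises(ValueError):
            tpc.aicc_select([m1, m2])

    def test_selection_invariant_to_data_ordering(self):
        data = sim.gen_aas_dataset(seed=3)
        shuffled = data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        with pytest.warns(UserWarning):
            fits = [tpc.fit_model(d, shape=s, seed=0)
                    for d in (data, shuffled) for s in ("gaussian", "quadratic")]
        best_orig, _ = tpc.aicc_select(fits[:2])
        best_shuf, _ = tpc.aicc_select(fits[2:])
        assert best_orig.shape == best_shuf.shape

    def test_gaussian_truth_selected_in_most_seeds(self):
        wins = 0
        n_runs = 100
        with pytest.warns(UserWarning):
            for seed in range(n_runs):
                data = sim.gen_aas_dataset(seed=seed)
                g = tpc.fit_model(data, "gaussian", n_starts=16, seed=seed)
                q = tpc.fit_model(data, "quadratic", n_starts=16, seed=seed)
                best, _ = tpc.aicc_select([g, q])
                wins += best.shape == "gaussian"
        assert wins >= 95


class TestDeriveParams:
    def _model(self):
        return tpc.TPCModel(
            "gaussian", {"a": 317.10, "t_opt": 29.15, "sigma": SIGMA_FROM_330},
            25, 1.0, 0.0,
        )

    def test_breadth_crossings_match_reported_window(self):
        d = tpc.derive_params(self._model())
        assert d.lower == pytest.approx(27.5, abs=1e-9)
        assert d.upper == pytest.approx(30.8, abs=1e-9)
        assert d.breadth == pytest.approx(3.30, abs=1e-9)

    def test_closed_form_agrees_with_root_finder(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            model = tpc.TPCModel(
                "gaussian",
                {"a": rng.uniform(50, 500), "t_opt": rng.uniform(20, 35),
                 "sigma": rng.uniform(0.5, 6.0)},
                25, 1.0, 0.0,
            )
            cf = tpc.derive_params(model, method="closed_form")
            rt = tpc.derive_params(model, method="root")
            assert abs(cf.lower - rt.lower) < 1e-8
            assert abs(cf.upper - rt.upper) < 1e-8

    def test_quadratic_crossings_and_peak(self):
        model = tpc.TPCModel("quadratic", {"c0": -1500.0, "c1": 120.0, "c2": -2.0},
                             25, 1.0, 0.0)
        d = tpc.derive_params(model)
        assert d.t_peak == pytest.approx(30.0)
        rt = tpc.derive_params(model, method="root")
        assert d.lower == pytest.approx(rt.lower, abs=1e-8)
        assert d.upper == pytest.approx(rt.upper, abs=1e-8)

    def test_quadratic_without_maximum_rejected(self):
        model = tpc.TPCModel("quadratic", {"c0": 0.0, "c1": 1.0, "c2": 0.5},
                             25, 1.0, 0.0)
        with pytest.raises(ValueError):
            tpc.derive_params(model)


class TestBootstrap:
    def test_zero_residuals_collapse_to_point_estimate(self):
        t, y = gaussian_data()
        model = tpc.fit_model((t, y), seed=0)
        result, intervals = tpc.bootstrap_bca(model, (t, y), n_boot=49, seed=0)
        for q in ("t_peak", "aas_max", "breadth"):
            row = intervals.loc[q]
            assert row["bca_low"] == pytest.approx(row["estimate"], rel=1e-6)
            assert row["bca_high"] == pytest.approx(row["estimate"], rel=1e-6)

    def test_symmetric_draws_reduce_to_percentile_interval(self):
        # with z0 = 0 and a = 0, BCa must equal the 2.5/97.5 percentiles
        draws = np.setdiff1d(np.linspace(-1.0, 1.0, 2001), [0.0])  # 1000 each side
        lo, hi = tpc._bca_interval(draws, 0.0, None, alpha=0.05)
        assert lo == pytest.approx(np.quantile(draws, 0.025), abs=1e-6)
        assert hi == pytest.approx(np.quantile(draws, 0.975), abs=1e-6)

    def test_intervals_cover_truth_on_noisy_data(self):
        data = sim.gen_aas_dataset(seed=4)
        with pytest.warns(UserWarning):
            model = tpc.fit_model(data, seed=4)
        result, intervals = tpc.bootstrap_bca(model, data, n_boot=199, seed=4)
        assert result.n_converged >= 0.8 * 199
        row = intervals.loc["t_peak"]
        assert row["bca_low"] < row["estimate"] < row["bca_high"]


class TestHolmSidak:
    def test_indistinguishable_groups_share_a_letter(self):
        g = {"27C": [1.0, 2.0, 3.0], "29C": [1.0, 2.0, 3.0], "31C": [1.0, 2.0, 3.0]}
        table, letters = tpc.holm_sidak_pairwise(g)
        assert (table["p_adjusted"] > 0.99).all()
        assert len(set(letters.values())) == 1

    def test_single_comparison_adjustment_is_identity(self):
        rng = np.random.default_rng(0)
        g = {"a": rng.normal(0, 1, 10), "b": rng.normal(5, 1, 10)}
        table, _ = tpc.holm_sidak_pairwise(g)
        assert table["p_adjusted"].iloc[0] == pytest.approx(table["p_raw"].iloc[0])

    def test_middle_group_differs_pattern(self):
        # 27 and 31 similar, 29 elevated: letters must read a / b / a
        rng = np.random.default_rng(3)
        g = {
            "27C": rng.normal(255.0, 25.0, 9),
            "29C": rng.normal(330.0, 25.0, 8),
            "31C": rng.normal(262.0, 25.0, 8),
        }
        table, letters = tpc.holm_sidak_pairwise(g)
        assert letters["27C"] == letters["31C"]
        assert letters["29C"] != letters["27C"]

    def test_zero_variance_everywhere_rejected(self):
        with pytest.raises(ValueError):
            tpc.holm_sidak_pairwise({"a": [1.0, 1.0], "b": [1.0, 1.0]})

    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=8, unique=True))
    def test_adjusted_p_monotone_and_at_least_raw(self, offsets):
        rng = np.random.default_rng(sum(offsets) % 2**31)
        groups = {f"g{i}": rng.normal(o / 100.0, 1.0, 6) for i, o in enumerate(offsets)}
        table, _ = tpc.holm_sidak_pairwise(groups)
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-12).all()
        ordered = table.sort_values("p_raw")
        assert ordered["p_adjusted"].is_monotonic_increasing
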