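import numpy as np
import pytest
from scipy import stats

from mucoquant import assays, synthetic
from mucoquant.stats_utils import holm_sidak


class TestStandardCurve:
    def test_exact_inversion(self):
        standards = [(c, 0.05 + 0.02 * c) for c in (0.0, 5.0, 10.0, 20.0)]
        concs, curve, extrap = assays.standard_curve_concentration(standards, [[0.25]])
        assert concs[0] == pytest.approx(10.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)
        assert not extrap[0]

    def test_duplicates_average(self):
        standards = [(c, 0.05 + 0.02 * c) for c in (0.0, 5.0, 10.0, 20.0)]
        dup, _, _ = assays.standard_curve_concentration(standards, [[0.24, 0.26]])
        single, _, _ = assays.standard_curve_concentration(standards, [[0.25]])
        assert dup[0] == pytest.approx(single[0], rel=1e-12)

    def test_extrapolation_flagged(self):
        standards = [(c, 0.05 + 0.02 * c) for c in (0.0, 5.0, 10.0)]
        _, _, extrap = assays.standard_curve_concentration(standards, [[0.9]])
        assert extrap[0]

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError):
            assays.standard_curve_concentration(
                [(0.0, 0.1), (5.0, 0.1), (10.0, 0.1)], [[0.1]]
            )

    def test_recovery_from_noisy_plates(self):
        errors = []
        for seed in range(100):
            plate = synthetic.simulate_plate_assay(
                [8.0], 0.02, 0.05, replicate_cv=0.05, n_replicates=2,
                standard_concentrations=np.linspace(0, 20, 6), seed=seed,
            )
            w = plate.wells
            stds = (
                w[w.role == "standard"].groupby("sample_id")
                .agg(conc=("concentration", "first"), a=("absorbance", "mean"))
            )
            unknowns = [w[w.role == "unknown"].absorbance.tolist()]
            concs, _, _ = assays.standard_curve_concentration(
                list(zip(stds.conc, stds.a)), unknowns
            )
            errors.append(abs(concs[0] - 8.0) / 8.0)
        assert np.median(errors) < 0.10


class TestDTNBKinetics:
    def test_noiseless_recovery(self):
        t = np.linspace(0, 100, 60)
        a = 0.1 + 0.7 * (1 - np.exp(-0.05 * t))
        fit = assays.dtnb_rate(t, a)
        assert fit.rate_constant == pytest.approx(0.05, abs=1e-6)
        assert fit.amplitude == pytest.approx(0.7, abs=1e-6)
        assert fit.rmse < 1e-9

    def test_flat_series(self):
        fit = assays.dtnb_rate(np.linspace(0, 10, 20), np.full(20, 0.3))
        assert fit.rate_constant == 0.0
        assert fit.amplitude == 0.0
        assert fit.baseline == pytest.approx(0.3)

    def test_noisy_recovery(self):
        ks = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            t = np.linspace(0, 100, 60)
            a = 0.1 + 0.7 * (1 - np.exp(-0.05 * t))
            a = a + rng.normal(0, 0.02 * 0.7, a.shape)
            ks.append(assays.dtnb_rate(t, a).rate_constant)
        assert abs(np.median(ks) - 0.05) / 0.05 < 0.10

    def test_rate_ratio_orders_agents(self):
        t = np.linspace(0, 100, 60)
        fast = assays.dtnb_rate(t, 0.1 + 0.7 * (1 - np.exp(-0.06 * t)))
        slow = assays.dtnb_rate(t, 0.1 + 0.7 * (1 - np.exp(-0.02 * t)))
        assert assays.rate_ratio(fast, slow) == pytest.approx(3.0, rel=1e-4)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            assays.dtnb_rate([0, 1, 2], [0.1, 0.2, 0.3])


class TestAEC:
    def test_fifty_percent_decrease(self):
        rep = assays.acute_endogenous_clearance([10.0, 10.0], [5.0, 5.0])
        assert rep["percent_decrease"] == pytest.approx(50.0)

    def test_identical_arms(self):
        rep = assays.acute_endogenous_clearance([5.0, 6.0, 7.0], [5.0, 6.0, 7.0])
        assert rep["percent_decrease"] == pytest.approx(0.0)
        assert rep["p"] > 0.95

    def test_zero_vehicle_mean_flagged(self):
        rep = assays.acute_endogenous_clearance([0.0, 0.0], [1.0, 2.0])
        assert rep["percent_decrease"] is None
        assert "percent_decrease" in rep["flags"]

    def test_power_at_planted_decrease(self):
        # 40% planted decrease, negative-binomial arms of 12 and 13
        hits = 0
        for seed in range(200):
            lav, _ = synthetic.simulate_lavage_experiment(
                [12, 13], [100.0, 60.0], dispersion=8.0, seed=seed,
                group_names=["vehicle", "treated"],
            )
            df = lav.counts
            rep = assays.acute_endogenous_clearance(
                df[df.group == "vehicle"].total_cells,
                df[df.group == "treated"].total_cells,
            )
            hits += rep["p"] < 0.05
        assert hits / 200 > 0.80


class TestSurvivalChisq:
    def test_identical_groups(self):
        chi2, df, p = assays.survival_chisq([(5, 20), (5, 20)])
        assert chi2 == 0.0
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        # {(10,20),(0,20)}: expected 5/15 per cell row -> chi2 = 40/3
        chi2, df, p = assays.survival_chisq([(10, 20), (0, 20)])
        assert chi2 == pytest.approx(40.0 / 3.0, rel=1e-12)
        assert df == 1

    def test_group_order_invariance(self):
        a = assays.survival_chisq([(10, 20), (0, 20), (3, 15)])
        b = assays.survival_chisq([(3, 15), (10, 20), (0, 20)])
        assert a[0] == pytest.approx(b[0], rel=1e-12)

    def test_small_expected_warns(self):
        with pytest.warns(UserWarning):
            assays.survival_chisq([(1, 2), (0, 2)])


class TestLinearRegimeViscosity:
    def test_flat_modulus(self):
        eta, info = assays.linear_regime_viscosity(
            np.arange(1, 9, dtype=float), np.full(8, 2.0), frequency=1.0
        )
        assert eta == pytest.approx(2.0)
        assert info["n_plateau"] == 8

    def test_shear_thinning_tail_excluded(self):
        stress = np.arange(1.0, 11.0)
        mod = np.concatenate([np.full(6, 2.0), 2.0 * (stress[6:] / stress[5]) ** -1.0])
        eta, info = assays.linear_regime_viscosity(stress, mod, frequency=1.0)
        assert eta == pytest.approx(2.0)
        assert info["n_plateau"] == 6

    def test_noisy_recovery(self):
        errs, no_regime = [], 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            stress = np.logspace(-2, 1, 20)
            mod = np.where(stress < 1, 3.0, 3.0 * stress**-0.7)
            mod = mod * (1 + rng.normal(0, 0.05, mod.shape))
            try:
                eta, _ = assays.linear_regime_viscosity(stress, mod, frequency=2.0)
                errs.append(abs(eta - 1.5) / 1.5)
            except ValueError:  # noise can legitimately hide the plateau
                no_regime += 1
                errs.append(np.nan)
        assert no_regime < 10
        assert np.nanmedian(errs) < 0.10

    def test_no_plateau_rejected(self):
        stress = np.arange(1.0, 8.0)
        mod = 10.0 * stress**-1.5  # immediately shear thinning
        with pytest.raises(ValueError):
            assays.linear_regime_viscosity(stress, mod, frequency=1.0)


class TestViscosityMassRegression:
    def test_exact_line(self):
        pairs = [(x, 2.0 * x + 1.0) for x in (1.0, 2.0, 3.0, 4.0)]
        rep = assays.viscosity_mass_regression(pairs)
        assert rep["slope"] == pytest.approx(2.0)
        assert rep["r"] == pytest.approx(1.0)

    def test_permutation_never_beats_exact_line(self):
        rng = np.random.default_rng(0)
        x = np.arange(1.0, 9.0)
        y = 2 * x + 1
        r_obs = abs(assays.viscosity_mass_regression(list(zip(x, y)))["r"])
        beats = 0
        for _ in range(500):
            yp = rng.permutation(y)
            if np.var(yp) > 0:
                r = abs(assays.viscosity_mass_regression(list(zip(x, yp)))["r"])
                beats += r >= r_obs and not np.allclose(yp, y)
        assert beats == 0

    def test_ols_slope_coverage(self):
        covered = 0
        for seed in range(200):
            rng = np.random.default_rng(seed)
            x = np.linspace(1, 10, 12)
            y = 1.0 + 0.5 * x + rng.normal(0, 0.5, x.size)
            res = stats.linregress(x, y)
            covered += abs(res.slope - 0.5) <= 2 * res.stderr
        assert covered / 200 >= 0.90

    def test_zero_mass_variance_rejected(self):
        with pytest.raises(ValueError):
            assays.viscosity_mass_regression([(1.0, 2.0), (1.0, 3.0), (1.0, 4.0)])


class TestGroupCompare:
    def test_identical_groups_any_method(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        for method in ("welch_t", "mann_whitney"):
            assert assays.group_compare(g, method=method)["p"] >= 0.99
        g3 = {"a": [1.0, 2.0], "b": [1.0, 2.0], "c": [1.0, 2.0]}
        assert assays.group_compare(g3, method="anova_holm_sidak")["p"] >= 0.99

    def test_mann_whitney_exact_enumeration(self):
        # U = 0 for {1,2,3} vs {4,5,6}; exact one-sided p = 1/C(6,3) = 0.05
        rep = assays.group_compare(
            {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]},
            method="mann_whitney", alternative="less",
        )
        assert rep["statistic"] == 0.0
        assert rep["p"] == pytest.approx(0.05, rel=1e-12)

    def test_anova_pairwise_adjustment_present(self):
        rng = np.random.default_rng(1)
        g = {k: rng.normal(i, 1, 8) for i, k in enumerate("abc")}
        rep = assays.group_compare(g, method="anova_holm_sidak")
        assert len(rep["pairwise"]) == 3
        for pw in rep["pairwise"]:
            assert pw["p_adjusted"] >= pw["p_raw"] - 1e-15

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            assays.group_compare({"a": [1.0], "b": [2.0]}, method="bogus")


class TestHolmSidak:
    def test_single_p_unchanged(self):
        assert holm_sidak([0.04])[0] == pytest.approx(0.04)

    def test_monotone_and_ordered(self):
        p = [0.01, 0.2, 0.03]
        adj = holm_sidak(p)
        assert adj[0] <= adj[2] <= adj[1]
        assert all(a >= raw - 1e-12 for a, raw in zip(adj, p))

    def test_matches_manual_formula(self):
        p = [0.01, 0.04, 0.03]
        adj = holm_sidak(p)
        # sorted: 0.01 (m=3), 0.03 (m=2), 0.04 (m=1), with running max
        e1 = 1 - (1 - 0.01) ** 3
        e2 = max(e1, 1 - (1 - 0.03) ** 2)
        e3 = max(e2, 1 - (1 - 0.04) ** 1)
        np.testing.assert_allclose(adj, [e1, e3, e2], rtol=1e-12)
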