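"""Selection-inference unit and property tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from phenosel.bootstrap import BootstrapConfig
from phenosel.selection import (
    ComparisonResult,
    SelectionEstimate,
    SelectionTable,
    compare_direct_vs_total,
    devtime_selection,
    direct_selection,
    fit_ols,
    fit_selection_model,
    pearson_correlation,
    prepare_analysis_frame,
    relativize,
    standardize,
    total_selection,
    vif,
)


class TestStandardize:
    def test_simple_vector(self):
        assert np.allclose(standardize([1.0, 2.0, 3.0]), [-1.0, 0.0, 1.0])

    def test_global_scheme_pooled_moments(self):
        x = np.array([1.0, 2.0, 3.0, 11.0, 12.0, 13.0])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        z = standardize(x, "global", g)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, rel=1e-12)
        # per-year means are NOT zero under the global scheme
        assert abs(z[g == "a"].mean()) > 0.5

    def test_local_scheme_per_group_moments(self):
        x = np.array([1.0, 2.0, 3.0, 11.0, 12.0, 13.0])
        g = np.array(["a", "a", "a", "b", "b", "b"])
        z = standardize(x, "local", g)
        for level in "ab":
            assert z[g == level].mean() == pytest.approx(0.0, abs=1e-12)
            assert z[g == level].std(ddof=1) == pytest.approx(1.0, rel=1e-12)

    def test_constant_vector_errors(self):
        with pytest.raises(ValueError, match="variance"):
            standardize([5.0, 5.0, 5.0])

    def test_zero_variance_group_named(self):
        with pytest.raises(ValueError, match="'y2'"):
            standardize([1.0, 2.0, 7.0, 7.0], "local", ["y1", "y1", "y2", "y2"])

    def test_unknown_scheme(self):
        with pytest.raises(ValueError, match="scheme"):
            standardize([1.0, 2.0], "within")


class TestRelativize:
    def test_simple_vector(self):
        assert np.allclose(relativize([0.0, 2.0, 4.0]), [0.0, 1.0, 2.0])

    def test_all_equal_identity(self):
        assert np.allclose(relativize([5.0, 5.0]), [1.0, 1.0])

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="zero"):
            relativize([0.0, 0.0, 0.0])

    def test_local_group_means_one(self):
        w = relativize([0.0, 4.0, 3.0, 3.0], "local", ["a", "a", "b", "b"])
        assert np.allclose(w, [0.0, 2.0, 1.0, 1.0])


class TestFitOls:
    def test_line_through_points(self):
        X = np.column_stack([np.ones(3), [0.0, 1.0, 2.0]])
        fit = fit_ols(X, [1.0, 2.0, 3.0])
        assert np.allclose(fit.params.to_numpy(), [1.0, 1.0])

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([np.ones(5), rng.normal(size=5), rng.normal(size=5)])
        y = rng.normal(size=5)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        fit = fit_ols(X, y)
        assert np.allclose(fit.params.to_numpy(), oracle, atol=1e-10)
        assert np.allclose(fit.fitted + fit.residuals, y)

    def test_duplicated_column_named(self):
        X = pd.DataFrame({"intercept": np.ones(4), "a": [1.0, 2, 3, 4], "b": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError, match="rank deficient.*'b'"):
            fit_ols(X, np.arange(4.0))


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        X = pd.DataFrame({"a": [1.0, -1, 1, -1], "b": [1.0, 1, -1, -1]})
        assert np.allclose(vif(X).to_numpy(), [1.0, 1.0])

    def test_bivariate_closed_form(self):
        # r = 0.5 between two predictors -> VIF = 1/(1-0.25) = 4/3
        rng = np.random.default_rng(1)
        a = rng.normal(size=4000)
        b = 0.5 * a + np.sqrt(1 - 0.25) * rng.normal(size=4000)
        r = np.corrcoef(a, b)[0, 1]
        expected = 1.0 / (1.0 - r**2)
        got = vif(pd.DataFrame({"a": a, "b": b}))
        assert np.allclose(got.to_numpy(), expected, rtol=1e-8)

    def test_duplicated_predictor_infinite(self):
        X = pd.DataFrame({"a": [1.0, 2, 3, 5], "b": [1.0, 2, 3, 5]})
        assert np.all(np.isinf(vif(X).to_numpy()))

    def test_single_predictor_rejected(self):
        with pytest.raises(ValueError, match="two"):
            vif(pd.DataFrame({"a": [1.0, 2, 3]}))


class TestPearson:
    def test_collinear(self):
        ct = pearson_correlation([1.0, 2, 3, 4], [2.0, 4, 6, 8])
        assert ct.r == pytest.approx(1.0)
        assert ct.p == pytest.approx(0.0, abs=1e-12)

    def test_formula_value(self):
        # r = 0.5, n = 27: t = 0.5*sqrt(25)/sqrt(0.75) = 2.8868
        rng = np.random.default_rng(3)
        for _ in range(50):
            x = rng.normal(size=27)
            y = rng.normal(size=27)
            ct = pearson_correlation(x, y)
            expected_t = ct.r * np.sqrt(25) / np.sqrt(1 - ct.r**2)
            assert ct.t == pytest.approx(expected_t, rel=1e-12)
            assert ct.df == 25
        # the worked constant itself
        t = 0.5 * np.sqrt(25) / np.sqrt(1 - 0.25)
        assert t == pytest.approx(2.8868, abs=1e-4)

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=40)
        y = 0.3 * x + rng.normal(size=40)
        ct = pearson_correlation(x, y)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert ct.r == pytest.approx(ref_r, rel=1e-10)
        assert ct.p == pytest.approx(ref_p, rel=1e-8)

    def test_null_type_one_error_rate(self):
        rng = np.random.default_rng(17)
        rejections = 0
        reps = 2000
        for _ in range(reps):
            ct = pearson_correlation(rng.normal(size=20), rng.normal(size=20))
            rejections += ct.p < 0.05
        assert 0.035 < rejections / reps < 0.065

    def test_too_short(self):
        with pytest.raises(ValueError, match="n >= 3"):
            pearson_correlation([1.0, 2.0], [3.0, 4.0])

    def test_zero_variance(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPrepareFrame:
    def test_single_year_local_equals_global(self, make_seasons):
        df = make_seasons(n_individuals=150, year_labels=(2013,), beta_ffd=-0.3, rng_seed=9)
        local = prepare_analysis_frame(df, "local")
        glob = prepare_analysis_frame(df, "global")
        for col in ("z_leafout", "z_ffd", "z_devtime", "z_size", "w"):
            assert np.allclose(local[col], glob[col], atol=1e-12)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            prepare_analysis_frame(pd.DataFrame({"year": [1]}), "local")


class TestTotalSelection:
    def test_recovers_solo_beta(self, make_seasons, quiet_clamp):
        df = make_seasons(
            n_individuals=5000,
            year_labels=(2013,),
            rho=0.0,
            beta_leafout=-0.5,
            zero_inflation_pi=0.0,
            mean_fitness=50.0,
            dispersion_k=20.0,
            rng_seed=21,
        )
        table = total_selection(df, "leaf_out_day")
        assert -0.55 < table["leaf_out_day"].estimate < -0.45

    def test_indirect_share_via_correlated_trait(self, make_seasons, quiet_clamp):
        # s_L = beta_L + rho * beta_F = 0 + 0.4 * (-0.5) = -0.2
        df = make_seasons(
            n_individuals=5000,
            year_labels=(2013,),
            rho=0.4,
            beta_leafout=0.0,
            beta_ffd=-0.5,
            zero_inflation_pi=0.0,
            mean_fitness=50.0,
            dispersion_k=20.0,
            rng_seed=22,
        )
        table = total_selection(df, "leaf_out_day")
        assert table["leaf_out_day"].estimate == pytest.approx(-0.2, abs=0.05)

    def test_zero_variance_fitness_zero_slopes(self, make_seasons):
        df = make_seasons(n_individuals=100, year_labels=(2013,), rng_seed=1)
        df["fitness_intact_seeds"] = 7.0
        table = total_selection(df, "leaf_out_day")
        for est in table.estimates:
            assert est.estimate == pytest.approx(0.0, abs=1e-10)

    def test_quadratic_excluded_on_request(self, make_seasons):
        df = make_seasons(n_individuals=80, year_labels=(2013,), rng_seed=2)
        table = total_selection(df, "leaf_out_day", include_quadratic=False)
        assert table.terms == ["leaf_out_day", "plant_size"]

    def test_no_size_variant(self, make_seasons):
        df = make_seasons(n_individuals=80, year_labels=(2013,), rng_seed=2)
        table = total_selection(df, "leaf_out_day", include_size=False)
        assert "plant_size" not in table.terms

    def test_unknown_trait(self, make_seasons):
        df = make_seasons(n_individuals=30, year_labels=(2013,), rng_seed=2)
        with pytest.raises(ValueError, match="unknown trait"):
            total_selection(df, "petal_count")


class TestSPBetaIdentity:
    @pytest.mark.parametrize(
        "rho,beta_l,beta_f",
        [(0.0, -0.3, 0.2), (0.3, -0.2, -0.3), (0.5, 0.25, -0.25), (-0.4, 0.2, 0.2)],
    )
    def test_total_equals_p_beta(self, make_seasons, rho, beta_l, beta_f):
        df = make_seasons(
            n_individuals=8000,
            year_labels=(2013,),
            rho=rho,
            beta_leafout=beta_l,
            beta_ffd=beta_f,
            zero_inflation_pi=0.0,
            mean_fitness=50.0,
            dispersion_k=50.0,
            rng_seed=int(1000 * (rho + 1) + 7),
        )
        s_l = total_selection(df, "leaf_out_day")["leaf_out_day"].estimate
        s_f = total_selection(df, "first_flowering_day")["first_flowering_day"].estimate
        assert s_l == pytest.approx(beta_l + rho * beta_f, abs=0.03)
        assert s_f == pytest.approx(beta_f + rho * beta_l, abs=0.03)


class TestDirectSelection:
    def test_recovers_both_gradients(self, make_seasons, quiet_clamp):
        df = make_seasons(
            n_individuals=5000,
            year_labels=(2013,),
            rho=0.4,
            beta_leafout=-0.3,
            beta_ffd=-0.5,
            zero_inflation_pi=0.0,
            mean_fitness=50.0,
            dispersion_k=20.0,
            rng_seed=31,
        )
        table = direct_selection(df)
        assert table["leaf_out_day"].estimate == pytest.approx(-0.3, abs=0.06)
        assert table["first_flowering_day"].estimate == pytest.approx(-0.5, abs=0.06)

    def test_near_collinear_reports_large_vif(self, make_seasons):
        df = make_seasons(n_individuals=400, year_labels=(2013,), rho=0.99, rng_seed=32)
        table = direct_selection(df)
        assert table["leaf_out_day"].vif > 10
        assert np.isfinite(table["leaf_out_day"].estimate)

    def test_recovers_correlational_coefficient(self, make_seasons, quiet_clamp):
        df = make_seasons(
            n_individuals=5000,
            year_labels=(2013,),
            rho=0.0,
            gamma_interaction=0.4,
            zero_inflation_pi=0.0,
            mean_fitness=50.0,
            dispersion_k=20.0,
            rng_seed=33,
        )
        table = direct_selection(df, full=True)
        inter = table["leaf_out_day:first_flowering_day"]
        assert 0.3 < inter.estimate < 0.5
        assert inter.doubled is False  # interaction not doubled by default

    def test_interaction_doubling_switch(self, make_seasons):
        df = make_seasons(n_individuals=200, year_labels=(2013,), rng_seed=34)
        plain = direct_selection(df, full=True)
        doubled = direct_selection(df, full=True, double_interaction=True)
        term = "leaf_out_day:first_flowering_day"
        assert doubled[term].estimate == pytest.approx(2 * plain[term].estimate, rel=1e-10)
        assert doubled[term].doubled is True


class TestDoublingConvention:
    def test_reported_quadratic_on_gamma_scale(self, make_seasons, quiet_clamp):
        # surface: w = 1 + 0.5*gamma*z^2; the raw regression coefficient is
        # gamma/2 and the doubled report recovers gamma.
        gamma = -0.4
        df = make_seasons(
            n_individuals=10_000,
            year_labels=(2013,),
            rho=0.0,
            gamma_ffd=gamma,
            zero_inflation_pi=0.0,
            mean_fitness=50.0,
            dispersion_k=20.0,
            rng_seed=41,
        )
        table = total_selection(df, "first_flowering_day")
        est = table["first_flowering_day^2"]
        assert est.doubled is True
        assert est.estimate == pytest.approx(gamma, abs=0.08)


class TestDevtimeSelection:
    def test_identity_and_code_path_equivalence(self, make_seasons):
        df = make_seasons(n_individuals=300, year_labels=(2013,), rng_seed=51)
        assert np.allclose(
            df["development_time"], df["first_flowering_day"] - df["leaf_out_day"]
        )
        a = devtime_selection(df)
        b = total_selection(df, "development_time")
        for ea, eb in zip(a.estimates, b.estimates):
            assert ea.estimate == pytest.approx(eb.estimate, rel=1e-12)

    def test_null_case_small_coefficient(self, make_seasons):
        df = make_seasons(
            n_individuals=4000,
            year_labels=(2013,),
            zero_inflation_pi=0.0,
            mean_fitness=50.0,
            dispersion_k=20.0,
            rng_seed=52,
        )
        table = devtime_selection(df)
        assert abs(table["development_time"].estimate) < 0.05

    def test_contrast_recovery_when_betas_opposed(self, make_seasons, quiet_clamp):
        # with beta_L = -beta_F and equal trait SDs, devtime = ffd - leafout
        # carries the fitness signal: slope on z_devtime is positive when
        # beta_F > 0 > beta_L scaled by the devtime SD geometry.
        df = make_seasons(
            n_individuals=8000,
            year_labels=(2013,),
            rho=0.3,
            beta_leafout=0.3,
            beta_ffd=-0.3,
            zero_inflation_pi=0.0,
            mean_fitness=50.0,
            dispersion_k=50.0,
            rng_seed=53,
        )
        # analytic contrast: cov(w, z_dev) with z_dev built from the same
        # standardized traits: s_dev = (beta_F - beta_L)(1 - rho)/sd_dev_z
        # where devtime = sd*(z_F - z_L) has variance 2(1-rho)*sd^2.
        expected = (-0.3 - 0.3) * (1 - 0.3) / np.sqrt(2 * (1 - 0.3))
        got = devtime_selection(df)["development_time"].estimate
        assert got == pytest.approx(expected, abs=0.04)


class TestInvariances:
    def test_row_order_and_relabeling_invariance(self, make_seasons):
        df = make_seasons(n_individuals=120, year_labels=(2013,), beta_ffd=-0.3, rng_seed=61)
        base = direct_selection(df)
        shuffled = df.sample(frac=1.0, random_state=0).reset_index(drop=True)
        shuffled["individual_id"] = [f"plant_{i}" for i in range(len(shuffled))]
        again = direct_selection(shuffled)
        for ea, eb in zip(base.estimates, again.estimates):
            assert ea.estimate == pytest.approx(eb.estimate, abs=1e-10)

    def test_single_year_local_equals_global_fit(self, make_seasons):
        df = make_seasons(n_individuals=150, year_labels=(2014,), beta_ffd=-0.3, rng_seed=62)
        a = direct_selection(df, scheme="local")
        b = direct_selection(df, scheme="global")
        for ea, eb in zip(a.estimates, b.estimates):
            assert ea.estimate == pytest.approx(eb.estimate, abs=1e-12)

    def test_gradient_recovery_bias_with_zero_inflation(self, make_seasons, quiet_clamp):
        # moderate betas, pi = 0.5: trait-independent zero inflation leaves
        # the gradients recoverable with small bias at large n
        df = make_seasons(
            n_individuals=20_000,
            year_labels=(2013,),
            rho=0.3,
            beta_leafout=-0.4,
            beta_ffd=0.3,
            zero_inflation_pi=0.5,
            mean_fitness=50.0,
            dispersion_k=20.0,
            rng_seed=63,
        )
        table = direct_selection(df)
        assert table["leaf_out_day"].estimate == pytest.approx(-0.4, abs=0.03)
        assert table["first_flowering_day"].estimate == pytest.approx(0.3, abs=0.03)


class TestBootstrappedTables:
    def test_intervals_and_flags_present(self, make_seasons):
        df = make_seasons(n_individuals=150, year_labels=(2013,), beta_ffd=-0.5, rng_seed=71)
        table = direct_selection(df, bootstrap=BootstrapConfig(n_replicates=400, rng_seed=5))
        for est in table.estimates:
            assert est.bca_lower is not None and est.bca_upper is not None
            assert est.bca_lower <= est.bca_upper
            assert est.significant == (not est.bca_lower <= 0 <= est.bca_upper)

    def test_deterministic_given_seed(self, make_seasons):
        df = make_seasons(n_individuals=100, year_labels=(2013,), rng_seed=72)
        cfg = BootstrapConfig(n_replicates=300, rng_seed=9)
        a = direct_selection(df, bootstrap=cfg)
        b = direct_selection(df, bootstrap=cfg)
        for ea, eb in zip(a.estimates, b.estimates):
            assert (ea.bca_lower, ea.bca_upper) == (eb.bca_lower, eb.bca_upper)


class TestCompareDirectVsTotal:
    def _estimate(self, term, estimate, lo=None, hi=None):
        return SelectionEstimate(
            term=term, estimate=estimate, bca_lower=lo, bca_upper=hi,
            significant=None if lo is None else not (lo <= 0 <= hi),
        )

    def test_flags_outside_interval(self):
        res = compare_direct_vs_total(
            self._estimate("leaf_out_day", -0.100),
            self._estimate("leaf_out_day", -0.262, -0.388, -0.135),
        )
        assert res.differs is True
        assert res.interpretation == "indirect via other trait"

    def test_equal_estimates_not_flagged(self):
        res = compare_direct_vs_total(
            self._estimate("leaf_out_day", -0.2),
            self._estimate("leaf_out_day", -0.2, -0.3, -0.1),
        )
        assert res.differs is False

    def test_boundary_not_flagged(self):
        res = compare_direct_vs_total(
            self._estimate("leaf_out_day", -0.3),
            self._estimate("leaf_out_day", -0.2, -0.3, -0.1),
        )
        assert res.differs is False

    def test_mismatched_terms_error(self):
        with pytest.raises(ValueError, match="term mismatch"):
            compare_direct_vs_total(
                self._estimate("leaf_out_day", -0.1),
                self._estimate("first_flowering_day", -0.2, -0.3, -0.1),
            )

    def test_table_year_mismatch_error(self, make_seasons):
        df = make_seasons(n_individuals=80, year_labels=(2013, 2014), rng_seed=81)
        cfg = BootstrapConfig(n_replicates=200, rng_seed=1)
        d13 = direct_selection(df, year=2013, bootstrap=cfg)
        t14 = total_selection(df, "leaf_out_day", year=2014, bootstrap=cfg)
        with pytest.raises(ValueError, match="year mismatch"):
            compare_direct_vs_total(d13, t14, term="leaf_out_day")

    def test_missing_interval_error(self, make_seasons):
        df = make_seasons(n_individuals=80, year_labels=(2013,), rng_seed=82)
        d = direct_selection(df)
        t = total_selection(df, "leaf_out_day")
        with pytest.raises(ValueError, match="no BCa interval"):
            compare_direct_vs_total(d, t, term="leaf_out_day")
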