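"""GRM construction and the REML mixed model: closed-form oracles,
invariances, and trend/group summaries."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from pedrec import SimConfig
from pedrec.grm import GRM, compute_grm
from pedrec.model import (RecombinationMixedModel, build_design,
                          estimate_heritability, fit_age_spline,
                          group_summary, temp_group_summary)
from pedrec.simulate import draw_crossover_count, simulate_rate_study


class TestGRM:
    def test_toy_matrix_matches_direct_formula(self):
        D = np.array([[0, 1, 2, 1],
                      [1, 1, 0, 2],
                      [2, 0, 1, 1]], dtype=float)
        g = compute_grm(D)
        p = D.mean(axis=0) / 2
        Z = D - 2 * p
        expected = Z @ Z.T / (2 * np.sum(p * (1 - p)))
        assert np.allclose(g.matrix, expected, atol=1e-10)
        assert np.allclose(g.matrix, g.matrix.T)

    def test_identical_genotypes_share_diagonal(self):
        D = np.array([[0, 1, 2, 0], [0, 1, 2, 0], [2, 1, 0, 1]], dtype=float)
        g = compute_grm(D).matrix
        assert g[0, 1] == pytest.approx(g[0, 0])
        assert g[0, 1] == pytest.approx(g[1, 1])

    def test_mean_diagonal_approaches_one_under_hwe(self, rng):
        D = rng.binomial(2, 0.5, size=(200, 5000))
        g = compute_grm(D)
        assert np.mean(np.diag(g.matrix)) == pytest.approx(1.0, abs=0.05)

    def test_monomorphic_markers_dropped_and_all_mono_rejected(self):
        D = np.array([[0, 2], [0, 2]], dtype=float)
        with pytest.raises(ValueError, match="monomorphic"):
            compute_grm(D)
        D2 = np.array([[0, 0, 1], [0, 2, 1], [0, 1, 0]], dtype=float)
        assert compute_grm(D2).n_markers == 2

    def test_missing_dosages_mean_imputed(self):
        D = np.array([[0, 1, 2], [1, -1, 0], [2, 1, 1]], dtype=float)
        g = compute_grm(D)
        Dm = D.copy()
        Dm[1, 1] = (0 + 1 + 2 - 1 + 1) / 2  # observed mean of column 1
        assert np.isfinite(g.matrix).all()


def _identity_grm(ids):
    return GRM(ids=list(ids), matrix=np.eye(len(ids)), n_markers=1)


def _toy_table(rng, n=60, n_parents=20):
    pids = [f"P{i}" for i in range(n_parents)]
    tab = pd.DataFrame({
        "parent_id": rng.choice(pids, n),
        "A": rng.integers(20, 120, n).astype(float),
        "B": rng.integers(2005, 2015, n).astype(float),
        "T1": rng.choice(["cold", "normal", "hot"], n),
        "T2": rng.choice(["cold", "normal", "hot"], n),
    })
    tab["A2"], tab["B2"] = tab["A"] ** 2, tab["B"] ** 2
    return tab, pids


class TestMixedModel:
    def test_identity_grm_reduces_to_ols(self, rng):
        """With G = I and no genetic variance the GLS fit equals OLS.

        Uses the centered design (the conditioning option): with uncentered
        year quadratics the comparison is dominated by the collinearity of
        B and B^2 rather than by the estimators themselves.
        """
        tab, _ = _toy_table(rng, n=120, n_parents=120)
        tab["parent_id"] = [f"P{i}" for i in range(120)]
        X = build_design(tab, center=True)
        beta = np.zeros(X.shape[1]); beta[0] = 1.0; beta[X.columns.get_loc("age")] = -0.05
        tab["Y"] = X.to_numpy() @ beta + rng.normal(0, 2.0, len(tab))
        grm = _identity_grm(tab["parent_id"])
        fit = RecombinationMixedModel(tab["Y"], X, grm, tab["parent_id"]).fit()
        ols = sm.OLS(tab["Y"].to_numpy(), X.to_numpy()).fit()
        assert np.allclose(fit.params, ols.params, atol=1e-6)
        assert fit.sigma_g2 == pytest.approx(0.0, abs=1e-8)

    def test_reml_optimum_beats_grid_search(self, rng):
        """The 1-D profiled optimum dominates a 50x50 grid over (sg2, se2)."""
        tab, pids = _toy_table(rng, n=50, n_parents=15)
        tab["Y"] = rng.normal(0, 3.0, 50) + rng.normal(0, 1.0, 50)
        G = np.eye(15) + 0.2
        grm = GRM(ids=[f"P{i}" for i in range(15)], matrix=G, n_markers=1)
        model = RecombinationMixedModel.from_dataframe(tab, grm)
        fit = model.fit()
        vy = float(np.var(tab["Y"]))
        grid_best = max(
            model.reml_loglike(sg, se)
            for sg in np.linspace(1e-4, 2 * vy, 50)
            for se in np.linspace(1e-3, 2 * vy, 50)
        )
        assert fit.llf >= grid_best - 1e-6

    def test_invariant_to_row_order_and_shift(self, rng):
        tab, _ = _toy_table(rng, n=80, n_parents=25)
        tab["Y"] = rng.normal(0, 3.0, 80)
        grm = _identity_grm(sorted(set(tab["parent_id"])))

        def fit(t):
            X = build_design(t, center=True)
            return RecombinationMixedModel(t["Y"], X, grm, t["parent_id"]).fit()

        f1 = fit(tab)
        perm = tab.sample(frac=1.0, random_state=1).reset_index(drop=True)
        f2 = fit(perm)
        assert np.allclose(f1.params, f2.params, atol=1e-6)
        assert f1.sigma_e2 == pytest.approx(f2.sigma_e2, rel=1e-5)
        shifted = tab.assign(Y=tab["Y"] + 5.0)
        f3 = fit(shifted)
        assert f3.params[0] == pytest.approx(f1.params[0] + 5.0, abs=1e-5)
        assert np.allclose(f3.params[1:], f1.params[1:], atol=1e-6)
        assert f3.sigma_e2 == pytest.approx(f1.sigma_e2, rel=1e-5)

    def test_rank_deficient_design_names_column(self, rng):
        tab, _ = _toy_table(rng, n=50, n_parents=10)
        tab["Y"] = rng.normal(size=50)
        X = build_design(tab)
        X["age_copy"] = X["age"]
        grm = _identity_grm(sorted(set(tab["parent_id"])))
        with pytest.raises(ValueError, match="rank deficient"):
            RecombinationMixedModel(tab["Y"], X, grm, tab["parent_id"])

    def test_heritability_recovered_from_generative_model(self, rng):
        """REML on simulated counts recovers h2 = 0.10 (single replicate,
        generous tolerance; the multi-replicate check runs at larger scale)."""
        cfg = SimConfig()
        rs = simulate_rate_study(cfg, 800, 1, rng, n_markers=600)
        grm = compute_grm(rs.dosages, rs.parent_ids)
        tab = rs.table.assign(Y=rs.table["r"].astype(float))
        fit = RecombinationMixedModel.from_dataframe(tab, grm).fit()
        assert 0.0 <= fit.h2 <= 1.0
        assert fit.h2 == pytest.approx(0.10, abs=0.08)
        assert fit.h2_se > 0

    def test_summary_lists_all_factors(self, rng):
        tab, _ = _toy_table(rng, n=60, n_parents=20)
        tab["Y"] = rng.normal(size=60)
        grm = _identity_grm(sorted(set(tab["parent_id"])))
        fit = RecombinationMixedModel.from_dataframe(tab, grm).fit()
        text = fit.summary()
        for name in ("T1[cold]", "T1[hot]", "T2[cold]", "T2[hot]",
                     "age", "birth_year", "h^2"):
            assert name in text
        assert len(fit.fixed_effects()) == 9  # intercept + 8 factors


class TestHeritability:
    def test_ratio(self):
        assert estimate_heritability(1.0, 9.0)[0] == pytest.approx(0.10)
        assert estimate_heritability(0.0, 5.0)[0] == 0.0

    def test_undefined_when_both_zero(self):
        with pytest.raises(ValueError):
            estimate_heritability(0.0, 0.0)

    def test_delta_method_se(self):
        cov = np.diag([0.04, 0.25])
        h2, se = estimate_heritability(1.0, 9.0, cov)
        grad = np.array([9.0, -1.0]) / 100.0
        assert se == pytest.approx(np.sqrt(grad @ cov @ grad))


class TestAgeSpline:
    def test_quadratic_minimum_recovered(self, rng):
        a = rng.integers(20, 121, 3000).astype(float)
        y = 0.002 * (a - 65.0) ** 2 + rng.normal(0, 1.0, a.size)
        fit = fit_age_spline(a, y)
        assert 55.0 <= fit.argmin_age <= 75.0

    def test_constant_response_flat(self, rng):
        a = rng.integers(20, 121, 500).astype(float)
        fit = fit_age_spline(a, np.full(500, 3.0))
        assert fit.fitted.max() - fit.fitted.min() < 1e-6

    def test_linear_noise_free_is_monotone(self):
        a = np.arange(20, 120, 2.0)
        fit = fit_age_spline(a, 0.3 * a - 1.0)
        assert np.all(np.diff(fit.fitted) > 0)

    def test_too_few_distinct_ages_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_age_spline(np.repeat([30.0, 40.0], 10), np.zeros(20))


class TestGroupSummaries:
    def test_hand_arithmetic(self):
        out = group_summary([2.0, 4.0], [1, 1])
        assert out.loc[0, "mean"] == pytest.approx(3.0)
        assert out.loc[0, "se"] == pytest.approx(1.0)

    def test_single_group_is_global(self, rng):
        y = rng.normal(size=40)
        out = group_summary(y, np.ones(40))
        assert out.loc[0, "mean"] == pytest.approx(y.mean())
        assert out.loc[0, "se"] == pytest.approx(y.std(ddof=1) / np.sqrt(40))

    def test_matches_streaming_oracle(self, rng):
        y = rng.normal(size=500)
        g = rng.integers(1, 11, 500)
        out = group_summary(y, g).set_index("group")
        for k in range(1, 11):
            vals = y[g == k]
            assert out.loc[k, "n"] == vals.size
            assert out.loc[k, "mean"] == pytest.approx(vals.mean())
            assert out.loc[k, "se"] == pytest.approx(vals.std(ddof=1) / np.sqrt(vals.size))

    def test_temperature_ordering_recovered(self, rng):
        """Generative hot > normal > cold effects show up in the category means."""
        cfg = SimConfig()
        n = 5000
        means = {}
        for cat, eff in (("cold", cfg.beta_cold), ("normal", 0.0), ("hot", cfg.beta_hot)):
            r = draw_crossover_count(cfg.base_rate_mu, eff, rng.normal(0, 3, n), rng)
            means[cat] = r.mean()
        y = np.concatenate([
            draw_crossover_count(cfg.base_rate_mu, eff, rng.normal(0, 3, n), rng)
            for eff in (cfg.beta_cold, 0.0, cfg.beta_hot)]).astype(float)
        cats = np.repeat(["cold", "normal", "hot"], n)
        out = temp_group_summary(y, cats).set_index("category")
        assert out.loc["hot", "mean"] > out.loc["normal", "mean"] > out.loc["cold", "mean"]

    def test_zero_iqr_for_identical_values(self):
        with pytest.warns(UserWarning):  # cold/normal absent in this toy
            out = temp_group_summary(np.full(10, 2.0), np.repeat("hot", 10))
        row = out.set_index("category").loc["hot"]
        assert row["q3"] - row["q1"] == 0.0

    def test_absent_category_warns_and_omits(self):
        with pytest.warns(UserWarning, match="cold"):
            out = temp_group_summary(np.ones(5), np.repeat("hot", 5))
        assert set(out["category"]) == {"hot"}
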