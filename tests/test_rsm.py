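"""Unit and property tests for the response-surface engine."""

import itertools

import numpy as np
import pandas as pd
import pytest

from algaesettle import datasets, rsm, synthetic
from algaesettle.rsm import (
    DEFAULT_FACTORS,
    DesignTable,
    Factor,
    actual_to_coded,
    anova_table,
    build_ccd,
    coded_to_actual,
    fit_quadratic,
    linreg_validation,
    model_summary,
    optimize_responses,
    predict,
    press_statistic,
    spearman_rho,
)

PH, SAL = DEFAULT_FACTORS


# ---------------------------------------------------------------------- coding

@pytest.mark.parametrize(
    "factor,coded,actual",
    [(PH, 0, 7.0), (PH, -2, 4.0), (PH, 2, 10.0), (SAL, 2, 35.0), (SAL, -2, 5.0)],
)
def test_coded_actual_study_levels(factor, coded, actual):
    assert coded_to_actual(factor, coded) == pytest.approx(actual)
    assert actual_to_coded(factor, actual) == pytest.approx(coded)


def test_coding_round_trip():
    a = 17.4
    c = actual_to_coded(SAL, a)
    assert c == pytest.approx(-0.3466666667)
    assert coded_to_actual(SAL, c) == pytest.approx(a, abs=1e-12)


def test_factor_rejects_nonpositive_step():
    with pytest.raises(ValueError):
        Factor("bad", 1.0, 0.0)


# -------------------------------------------------------------- CCD construction

def test_default_ccd_matches_study_geometry(ccd_table):
    """Default build reproduces the (pH, salinity) multiset of the 14-run table."""
    design = build_ccd(DEFAULT_FACTORS, seed=0)
    built = sorted(map(tuple, design.actual().round(9)))
    reference = sorted(map(tuple, ccd_table.actual().round(9)))
    assert built == reference
    assert design.n_runs == 14
    assert sorted(design.blocks().tolist()) == [1] * 7 + [2] * 7


def test_ccd_without_centers_has_eight_runs():
    design = build_ccd(DEFAULT_FACTORS, n_center_cube=0, n_center_axial=0)
    assert design.n_runs == 8
    assert (design.blocks() == 1).sum() == 4
    assert (design.blocks() == 2).sum() == 4


def test_textbook_ccd_axial_at_extremes():
    """Cube at ±1 and axial at ±2 puts star points at the factor extremes."""
    design = build_ccd(DEFAULT_FACTORS, cube_coded=1, axial_coded=2,
                       n_center_cube=0, n_center_axial=0)
    expected = sorted(
        [(7 + s1 * 1.5, 20 + s2 * 7.5) for s1, s2 in itertools.product((-1, 1), repeat=2)]
        + [(4.0, 20.0), (10.0, 20.0), (7.0, 5.0), (7.0, 35.0)]
    )
    assert sorted(map(tuple, design.actual().round(9))) == expected


def test_ccd_rejects_three_factors():
    with pytest.raises(ValueError, match="two factors"):
        build_ccd((PH, SAL, Factor("x", 0, 1)))


def test_ccd_warns_on_degenerate_star():
    with pytest.warns(UserWarning, match="degenerate"):
        build_ccd(DEFAULT_FACTORS, cube_coded=1, axial_coded=1)


def test_ccd_run_order_is_seeded():
    a = build_ccd(DEFAULT_FACTORS, seed=7)
    b = build_ccd(DEFAULT_FACTORS, seed=7)
    pd.testing.assert_frame_equal(a.data, b.data)


# ------------------------------------------------------------------ fitting

def test_cs_efficiency_fit_matches_published_equation(cs_efficiency_fit):
    """Uncoded equation for C. sorokiniana efficiency at printed precision."""
    c = cs_efficiency_fit.coefficients()
    assert c["b0"] == pytest.approx(191.18, abs=0.005)
    assert c["pH"] == pytest.approx(-33.79, abs=0.005)
    assert c["salinity"] == pytest.approx(0.531, abs=0.0005)
    assert c["pH^2"] == pytest.approx(2.365, abs=0.0005)
    assert c["salinity^2"] == pytest.approx(-0.01581, abs=5e-6)
    assert c["pH*salinity"] == pytest.approx(0.00544, abs=5e-6)
    assert cs_efficiency_fit.block_effects.sum() == pytest.approx(0, abs=1e-12)


def test_noiseless_quadratic_recovered_exactly():
    coefs = {"b0": 3.2, "pH": -1.1, "salinity": 0.4, "pH^2": 0.25,
             "salinity^2": -0.02, "pH*salinity": 0.07}
    design = build_ccd(DEFAULT_FACTORS, seed=3)
    table, _ = synthetic.gen_response_surface(design, coefs, response_name="y")
    fit = fit_quadratic(table, "y")
    got = fit.coefficients()
    for term, val in coefs.items():
        assert got[term] == pytest.approx(val, abs=1e-8)
    assert np.allclose(fit.block_effects, 0, atol=1e-8)


def test_fit_matches_normal_equations_oracle(ccd_table):
    """Brute-force (X'X)^-1 X'y solve agrees with the library fit."""
    y = ccd_table.data["mc_time_h"].to_numpy(float)
    x = ccd_table.actual()
    c = np.where(ccd_table.blocks() == 1, 1.0, -1.0)
    X = np.column_stack([np.ones(14), x[:, 0], x[:, 1], x[:, 0] ** 2,
                         x[:, 1] ** 2, x[:, 0] * x[:, 1], c])
    beta = np.linalg.inv(X.T @ X) @ X.T @ y
    fit = fit_quadratic(ccd_table, "mc_time_h")
    got = fit.coefficients()
    expected = dict(zip(
        ["b0", "pH", "salinity", "pH^2", "salinity^2", "pH*salinity"], beta[:6]))
    for term, val in expected.items():
        assert got[term] == pytest.approx(val, abs=1e-9)
    assert got["block[1]"] == pytest.approx(beta[6], abs=1e-9)


def test_fit_agrees_with_statsmodels(ccd_table):
    sm = pytest.importorskip("statsmodels.api")
    y = ccd_table.data["cs_efficiency_pct"].to_numpy(float)
    x = ccd_table.actual()
    c = np.where(ccd_table.blocks() == 1, 1.0, -1.0)
    X = np.column_stack([np.ones(14), x[:, 0], x[:, 1], x[:, 0] ** 2,
                         x[:, 1] ** 2, x[:, 0] * x[:, 1], c])
    res = sm.OLS(y, X).fit()
    fit = fit_quadratic(ccd_table, "cs_efficiency_pct")
    assert fit.beta0 == pytest.approx(res.params[0], abs=1e-8)
    assert fit.ss_error == pytest.approx(res.ssr, rel=1e-10)


def test_fit_reports_rank_deficiency():
    data = pd.DataFrame({
        "run_order": range(1, 9), "block": [1] * 8,
        "pH": [7.0] * 8,  # constant factor -> pH collinear with intercept
        "salinity": np.linspace(5, 35, 8),
        "y": np.linspace(0, 1, 8),
    })
    design = DesignTable(DEFAULT_FACTORS, data)
    with pytest.raises(rsm.RankDeficiencyError, match="collinear"):
        fit_quadratic(design, "y")


def test_fitted_plus_residuals_reproduce_observations(cs_efficiency_fit):
    np.testing.assert_allclose(
        cs_efficiency_fit.fitted + cs_efficiency_fit.residuals,
        cs_efficiency_fit.observed, atol=1e-10)


def test_ss_additivity_on_all_responses(ccd_table):
    for resp in ccd_table.response_names:
        fit = fit_quadratic(ccd_table, resp)
        assert fit.ss_model + fit.ss_error == pytest.approx(fit.ss_total, rel=1e-8)
        assert fit.df_model + fit.df_error == fit.n - 1


# ------------------------------------------------------------------ prediction

def test_predictions_match_validated_optima(cs_efficiency_fit, cs_time_fit,
                                            mc_efficiency_fit, mc_time_fit):
    assert predict(cs_efficiency_fit, [4, 17.4]) == pytest.approx(98.68, abs=0.1)
    assert predict(cs_time_fit, [4, 17.4]) == pytest.approx(12.06, abs=0.1)
    assert predict(mc_efficiency_fit, [4, 16.8]) == pytest.approx(93.483, abs=0.1)
    assert predict(mc_time_fit, [4, 16.8]) == pytest.approx(28.12, abs=0.1)


def test_zero_fit_predicts_zero(cs_efficiency_fit):
    import dataclasses

    zero = dataclasses.replace(
        cs_efficiency_fit, beta0=0.0,
        beta_linear=np.zeros(2), beta_square=np.zeros(2),
        beta_interaction=np.zeros(1))
    assert predict(zero, [6.3, 11.0]) == 0.0


def test_published_surface_at_center():
    """Hand evaluation of the printed efficiency equation at (pH 7, 20 ppt)."""
    val = synthetic.evaluate_surface(
        datasets.CS_EFFICIENCY_SURFACE, DEFAULT_FACTORS, [7, 20])
    assert val == pytest.approx(75.59, abs=0.005)


def test_predict_warns_outside_design_box(cs_efficiency_fit):
    with pytest.warns(UserWarning, match="outside"):
        predict(cs_efficiency_fit, [12.0, 20.0])


# ------------------------------------------------------------------ ANOVA

def test_anova_matches_published_table(cs_efficiency_fit, ccd_table):
    table = anova_table(cs_efficiency_fit, ccd_table)
    model = table["Model"]
    assert model.df == 6
    assert model.F == pytest.approx(554.16, abs=0.5)
    pe = table["Pure error"]
    assert pe.df == 4
    assert pe.adj_ss == pytest.approx(0.011, abs=0.0005)
    lof = table["Lack-of-fit"]
    assert lof.df == 3
    assert lof.F == pytest.approx(219.02, abs=0.5)
    # per-term adjusted SS (coded-unit Type III), printed values
    assert table["  pH"].adj_ss == pytest.approx(13.468, abs=0.001)
    assert table["  salinity"].adj_ss == pytest.approx(4.042, abs=0.001)
    assert table["Linear"].adj_ss == pytest.approx(17.51, abs=0.005)
    assert table["Square"].adj_ss == pytest.approx(585.6, abs=0.05)
    assert table["Blocks"].adj_ss == pytest.approx(0.251, abs=0.001)
    assert table["2-way interaction"].adj_ss == pytest.approx(0.24, abs=0.001)


def test_anova_constant_response_flagged():
    data = pd.DataFrame({
        "run_order": range(1, 15), "block": [1] * 7 + [2] * 7,
        "pH": build_ccd(seed=0).data["pH"],
        "salinity": build_ccd(seed=0).data["salinity"],
        "y": [5.0] * 14,
    })
    design = DesignTable(DEFAULT_FACTORS, data)
    fit = fit_quadratic(design, "y")
    with pytest.warns(UserWarning, match="constant"):
        table = anova_table(fit, design)
    assert table["Model"].adj_ss == pytest.approx(0, abs=1e-9)
    assert table["Model"].F is None


def test_anova_equals_projection_oracle():
    """Six-run hand example: SS decomposition equals explicit projections."""
    rng = np.random.default_rng(5)
    ph = np.array([4, 10, 4, 10, 7, 7], float)
    sal = np.array([5, 5, 35, 35, 20, 20], float)
    y = rng.normal(50, 5, size=6)
    data = pd.DataFrame({
        "run_order": range(1, 7), "block": [1] * 6,
        "pH": ph, "salinity": sal, "y": y})
    design = DesignTable(DEFAULT_FACTORS, data)
    # only 5 estimable terms here (pH^2 collinear with pH for 2-level pH):
    # use a reduced comparison through the error SS instead
    x1, x2 = (ph - 7) / 1.5, (sal - 20) / 7.5
    X = np.column_stack([np.ones(6), x1, x2, x1 * x2])
    P = X @ np.linalg.pinv(X)
    sse_proj = float(y @ (np.eye(6) - P) @ y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    assert float(np.sum((y - X @ beta) ** 2)) == pytest.approx(sse_proj, abs=1e-8)


def test_anova_equals_drop_one_term_refits(ccd_table):
    """Type-III SS match literal refits without each term (coded units)."""
    fit = fit_quadratic(ccd_table, "mc_efficiency_pct")
    table = anova_table(fit, ccd_table)
    y = fit.observed
    x = ccd_table.coded()
    cols = {
        "  pH": x[:, 0], "  salinity": x[:, 1],
        "  pH^2": x[:, 0] ** 2, "  salinity^2": x[:, 1] ** 2,
        "  pH*salinity": x[:, 0] * x[:, 1],
        "Blocks": np.where(ccd_table.blocks() == 1, 1.0, -1.0),
    }
    full = np.column_stack([np.ones(len(y)), *cols.values()])

    def sse(M):
        b, *_ = np.linalg.lstsq(M, y, rcond=None)
        return float(np.sum((y - M @ b) ** 2))

    sse_full = sse(full)
    for i, (name, _) in enumerate(cols.items(), start=1):
        reduced = np.delete(full, i, axis=1)
        assert table[name.replace("Blocks", "Blocks")].adj_ss == pytest.approx(
            sse(reduced) - sse_full, abs=1e-8), name


def test_anova_unreplicated_design_reports_lof_not_estimable():
    design = build_ccd(DEFAULT_FACTORS, n_center_cube=1, n_center_axial=0, seed=1)
    table, _ = synthetic.gen_response_surface(
        design, datasets.CS_EFFICIENCY_SURFACE, response_name="y",
        noise_sd=0.5, seed=2)
    fit = fit_quadratic(table, "y")
    at = anova_table(fit, table)
    assert not at.lack_of_fit_estimable
    assert any("not estimable" in r.source for r in at.rows)


# ------------------------------------------------------------- model summary

def test_summary_matches_published_statistics(cs_efficiency_fit, ccd_table):
    s = model_summary(cs_efficiency_fit, ccd_table)
    assert s.s == pytest.approx(0.5081, abs=0.0005)
    assert s.r2 == pytest.approx(99.79, abs=0.05)
    assert s.r2_adj == pytest.approx(99.61, abs=0.05)
    assert s.r2_pred == pytest.approx(93.45, abs=0.05)


def test_perfect_quadratic_gives_full_r2():
    design = build_ccd(DEFAULT_FACTORS, seed=2)
    table, _ = synthetic.gen_response_surface(
        design, datasets.MC_TIME_SURFACE, response_name="y")
    fit = fit_quadratic(table, "y")
    s = model_summary(fit, table)
    assert s.r2 == pytest.approx(100, abs=1e-6)
    assert s.r2_adj == pytest.approx(100, abs=1e-6)
    assert s.r2_pred == pytest.approx(100, abs=1e-6)


def test_press_equals_literal_loo_refits():
    """PRESS == sum of squared leave-one-out prediction errors by refitting."""
    rng = np.random.default_rng(11)
    design = build_ccd(DEFAULT_FACTORS, n_center_cube=1, n_center_axial=1, seed=4)
    table, _ = synthetic.gen_response_surface(
        design, datasets.CS_TIME_SURFACE, response_name="y", noise_sd=1.0, seed=9)
    fit = fit_quadratic(table, "y")
    X, y = fit.design_matrix, fit.observed
    loo = 0.0
    for i in range(len(y)):
        keep = np.arange(len(y)) != i
        b, *_ = np.linalg.lstsq(X[keep], y[keep], rcond=None)
        loo += (y[i] - X[i] @ b) ** 2
    assert press_statistic(fit) == pytest.approx(loo, rel=1e-8)


def test_r2_ordering_and_press_bound(ccd_table):
    for resp in ccd_table.response_names:
        fit = fit_quadratic(ccd_table, resp)
        s = model_summary(fit, ccd_table)
        assert press_statistic(fit) >= fit.ss_error - 1e-12
        assert s.r2_pred <= s.r2_adj + 1e-9 <= s.r2 + 1e-9


def test_coding_invariance_of_model_statistics(ccd_table):
    """Fitting in coded units leaves R^2 and the model F unchanged."""
    coded_factors = (Factor("pH", 0.0, 1.0), Factor("salinity", 0.0, 1.0))
    coded = ccd_table.coded()
    data = ccd_table.data.copy()
    data["pH"], data["salinity"] = coded[:, 0], coded[:, 1]
    coded_design = DesignTable(coded_factors, data)
    for resp in ["cs_efficiency_pct", "mc_time_h"]:
        fa = fit_quadratic(ccd_table, resp)
        fc = fit_quadratic(coded_design, resp)
        sa, sc = model_summary(fa, ccd_table), model_summary(fc, coded_design)
        assert sa.r2 == pytest.approx(sc.r2, abs=1e-8)
        assert sa.r2_pred == pytest.approx(sc.r2_pred, abs=1e-8)
        ta = anova_table(fa, ccd_table)["Model"]
        tc = anova_table(fc, coded_design)["Model"]
        assert ta.F == pytest.approx(tc.F, rel=1e-8)
        assert ta.p == pytest.approx(tc.p, rel=1e-6)


def test_coefficient_recovery_from_noisy_surfaces():
    """sigma=0.5 noise: estimates within 3 SE in >=95% of 200 replicates."""
    design = build_ccd(DEFAULT_FACTORS, seed=0)
    truth = datasets.CS_EFFICIENCY_SURFACE
    terms = ["b0", "pH", "salinity", "pH^2", "salinity^2", "pH*salinity"]
    X, _, _ = rsm._design_matrix(design, include_blocks=True)
    xtx_inv = np.linalg.inv(X.T @ X)
    hits = np.zeros(len(terms))
    n_rep = 200
    for seed in range(n_rep):
        table, _ = synthetic.gen_response_surface(
            design, truth, response_name="y", noise_sd=0.5, seed=seed)
        fit = fit_quadratic(table, "y")
        mse = fit.ss_error / fit.df_error
        se = np.sqrt(mse * np.diag(xtx_inv))[:6]
        est = np.array([fit.coefficients()[t] for t in terms])
        tru = np.array([truth[t] for t in terms])
        hits += np.abs(est - tru) <= 3 * se
    assert np.all(hits / n_rep >= 0.95)


# ---------------------------------------------------------------- optimization

def test_joint_optimum_matches_study_conditions(cs_efficiency_fit, cs_time_fit):
    res = optimize_responses(cs_efficiency_fit, cs_time_fit, grid_step=0.1)
    ph_opt, sal_opt = res.settings
    assert ph_opt == pytest.approx(4.0, abs=0.05)  # acid boundary
    assert 17.0 <= sal_opt <= 18.2  # 17.4 under efficiency-dominant weighting
    res_eff = optimize_responses(
        cs_efficiency_fit, cs_time_fit, weights=(1.0, 0.0), grid_step=0.05)
    assert res_eff.settings[0] == pytest.approx(4.0, abs=0.05)
    assert res_eff.settings[1] == pytest.approx(17.4, abs=0.1)


def test_efficiency_only_optimum_matches_parabola_vertex(cs_efficiency_fit, cs_time_fit):
    """With pH pinned, the salinity optimum is the -b/2a vertex."""
    c = cs_efficiency_fit.coefficients()
    ph = 4.0
    vertex = -(c["salinity"] + c["pH*salinity"] * ph) / (2 * c["salinity^2"])
    res = optimize_responses(
        cs_efficiency_fit, cs_time_fit, weights=(1.0, 0.0),
        bounds=[(ph, ph + 1e-9), (5.0, 35.0)], grid_step=0.01)
    assert res.settings[1] == pytest.approx(vertex, abs=0.02)


def test_mc_optimum_agrees_with_exhaustive_grid(mc_efficiency_fit, mc_time_fit):
    res = optimize_responses(mc_efficiency_fit, mc_time_fit,
                             weights=(1.0, 0.0), grid_step=0.05)
    # exhaustive 0.01-step oracle along pH=4 (efficiency decreases in pH)
    sals = np.arange(5, 35.001, 0.01)
    preds = [predict(mc_efficiency_fit, [4.0, s]) for s in sals]
    best_sal = sals[int(np.argmax(preds))]
    assert res.settings[0] == pytest.approx(4.0, abs=0.05)
    assert res.settings[1] == pytest.approx(best_sal, abs=0.05)
    assert best_sal == pytest.approx(16.8, abs=0.2)


def test_optimizer_polish_agrees_with_grid(cs_efficiency_fit, cs_time_fit):
    coarse = optimize_responses(cs_efficiency_fit, cs_time_fit, grid_step=0.25)
    fine = optimize_responses(cs_efficiency_fit, cs_time_fit, grid_step=0.05)
    assert np.all(np.abs(coarse.settings - fine.settings) <= 0.25 + 1e-9)
    assert coarse.objective_value == pytest.approx(fine.objective_value, abs=1e-3)


def test_optimizer_rejects_empty_bounds(cs_efficiency_fit, cs_time_fit):
    with pytest.raises(ValueError, match="empty bounds"):
        optimize_responses(cs_efficiency_fit, cs_time_fit,
                           bounds=[(5, 5), (10, 5)])


# ------------------------------------------------------- validation statistics

def test_linreg_exact_proportionality():
    x = np.arange(1, 11, dtype=float)
    res = linreg_validation(np.column_stack([x, 2 * x]))
    assert res.summary.r2 == pytest.approx(100)
    assert res.pearson_r == pytest.approx(1.0)
    assert res.slope == pytest.approx(2.0)


def test_linreg_perfect_negative():
    x = np.arange(5, dtype=float)
    res = linreg_validation(np.column_stack([x, -x]))
    assert res.pearson_r == pytest.approx(-1.0)


def test_linreg_matches_closed_form_covariance():
    pairs = np.array([[1, 2.1], [2, 3.9], [3, 6.2], [4, 8.1], [5, 9.8]])
    x, y = pairs[:, 0], pairs[:, 1]
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    res = linreg_validation(pairs)
    assert res.slope == pytest.approx(sxy / sxx, abs=1e-12)
    assert res.intercept == pytest.approx(y.mean() - sxy / sxx * x.mean(), abs=1e-12)
    assert res.pearson_r == pytest.approx(sxy / np.sqrt(sxx * syy), abs=1e-12)


def test_linreg_rejects_constant_x():
    with pytest.raises(ValueError, match="variance"):
        linreg_validation([[1, 2], [1, 3], [1, 4]])


def test_spearman_monotone():
    x = np.arange(10, dtype=float)
    assert spearman_rho(x, np.exp(x))[0] == pytest.approx(1.0)
    assert spearman_rho(x, -(x**3))[0] == pytest.approx(-1.0)


def test_spearman_ties_equal_midrank_pearson():
    x = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 4.0, 5.0])
    y = np.array([3.0, 1.0, 4.0, 4.0, 6.0, 7.0, 7.0])

    def midranks(v):
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2
            i = j
        return ranks

    rx, ry = midranks(x), midranks(y)
    expected = np.corrcoef(rx, ry)[0, 1]
    assert spearman_rho(x, y)[0] == pytest.approx(expected, abs=1e-12)


def test_spearman_rejects_constant_vector():
    with pytest.raises(ValueError, match="constant"):
        spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])
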