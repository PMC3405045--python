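"""AICc machinery, mixed-model fitting oracles, and helper statistics."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from billheat.model_selection import (
    ModelFit,
    ModelSpec,
    aggregate_steps,
    aicc,
    build_model_set,
    compare_models,
    design_matrix,
    evidence_ratio,
    fit_model,
    model_average_predictions,
    pooled_t_bonferroni,
    residual_correlogram,
)
from billheat.synthetic import CohortConfig, generate_cohort, generate_experiment

# --- candidate sets and parameter accounting -------------------------------


def test_model_set_parameter_accounting():
    """K bookkeeping: fixed coefficients + intercept + sqrt_activity + 2 variances."""
    specs = {s.label: s for s in build_model_set("t_bill")}
    assert specs["SSP + Ta"].k == 6
    assert specs["SSP * Ta"].k == 7
    assert specs["SSP + Ta + Ta^2"].k == 7
    assert specs["SSP * Ta + SSP * Ta^2"].k == 9
    assert specs["SSP * Ta + SSP * Ta^2 + SSP * Ta^3"].k == 11
    assert specs["1"].k == 4
    assert len(specs) == 11


def test_model_set_respects_marginality():
    for spec in build_model_set("t_base"):
        terms = set(spec.terms)
        if "ta3" in terms:
            assert {"ta", "ta2"} <= terms
        for inter in ("ssp:ta", "ssp:ta2", "ssp:ta3"):
            if inter in terms:
                assert "ssp" in terms and inter.split(":")[1] in terms


def test_invalid_specs_rejected():
    with pytest.raises(ValueError, match="unknown"):
        build_model_set("bill_color")
    with pytest.raises(ValueError, match="main effects"):
        ModelSpec("t_bill", ("ta", "ssp:ta"), "bad")
    with pytest.raises(ValueError, match="ta2"):
        ModelSpec("t_bill", ("ta", "ta3"), "bad")


def test_design_matrix_columns(step_data):
    X = design_matrix(step_data, ("ssp", "ta", "ssp:ta"))
    assert list(X.columns) == ["intercept", "ssp", "ta", "ssp:ta", "sqrt_activity"]
    assert set(X["ssp"].unique()) == {0.0, 1.0}


# --- AICc, weights, evidence ratios ---------------------------------------


def test_aicc_values():
    assert aicc(0.0, 0, 10) == 0.0
    assert aicc(-100.0, 6, 216) == pytest.approx(200 + 12 + 84 / 209)
    # converges to plain AIC as n grows
    assert aicc(-100.0, 6, 10**7) == pytest.approx(212.0, abs=1e-4)
    with pytest.raises(ValueError, match="AICc undefined"):
        aicc(-10.0, 6, 7)


def _dummy_fit(label, loglik, prediction, se=0.0, n=216):
    spec = ModelSpec("t_bill", (), label)
    coef = pd.Series({"intercept": prediction, "sqrt_activity": 0.0})
    cov = pd.DataFrame(
        [[se**2, 0.0], [0.0, 0.0]], index=coef.index, columns=coef.index
    )
    return ModelFit(
        spec=spec, coefficients=coef, cov_fixed=cov,
        random_intercept_var=0.0, residual_var=1.0, loglik=loglik, n=n,
    )


GRID = pd.DataFrame({"subspecies": ["melodia"], "ta": [26.0], "activity": [0.0]})


def test_equal_aicc_gives_equal_weights():
    comp = compare_models([_dummy_fit("A", -100.0, 10.0), _dummy_fit("B", -100.0, 12.0)])
    assert comp.weight("A") == pytest.approx(0.5)
    assert comp.weight("B") == pytest.approx(0.5)


def test_delta_two_weights():
    comp = compare_models([_dummy_fit("A", -100.0, 10.0), _dummy_fit("B", -101.0, 12.0)])
    assert comp.table["delta_aicc"].tolist() == pytest.approx([0.0, 2.0])
    assert comp.weight("A") == pytest.approx(0.731, abs=5e-4)
    assert comp.weight("B") == pytest.approx(0.269, abs=5e-4)


def test_comparison_invariants(step_data):
    fits = [fit_model(step_data, s) for s in build_model_set("t_bill")[:5]]
    comp = compare_models(fits)
    assert comp.table["weight"].sum() == pytest.approx(1.0)
    assert comp.table["delta_aicc"].iloc[0] == 0.0
    assert (comp.table["delta_aicc"] >= 0).all()
    assert comp.table["aicc"].is_monotonic_increasing
    assert (comp.display_table(5.0)["delta_aicc"] < 5.0).all()


def test_evidence_ratio():
    comp = compare_models([_dummy_fit("A", -100.0, 10.0), _dummy_fit("B", -104.0, 12.0)])
    assert evidence_ratio(comp, "A", "A") == 1.0
    r = evidence_ratio(comp, "A", "B")
    assert r == pytest.approx(np.exp(4.0))
    assert r * evidence_ratio(comp, "B", "A") == pytest.approx(1.0)
    # the published headline arises as a plain weight ratio
    assert 0.72 / 0.0141 == pytest.approx(51.06, abs=0.01)


def test_model_average_single_model_is_identity():
    fit = _dummy_fit("A", -100.0, 10.0, se=0.5)
    comp = compare_models([fit])
    out = model_average_predictions(comp, GRID)
    assert out["fit"].iloc[0] == pytest.approx(10.0)
    assert out["unconditional_se"].iloc[0] == pytest.approx(0.5)


def test_model_average_two_model_closed_form():
    """Equal weights, predictions 10 and 12, zero SEs -> mean 11, SE 1."""
    comp = compare_models([_dummy_fit("A", -100.0, 10.0), _dummy_fit("B", -100.0, 12.0)])
    out = model_average_predictions(comp, GRID)
    assert out["fit"].iloc[0] == pytest.approx(11.0)
    assert out["unconditional_se"].iloc[0] == pytest.approx(1.0)


def test_unconditional_se_at_least_weighted_component_floor(step_data):
    fits = [fit_model(step_data, s) for s in build_model_set("t_bill")[:4]]
    comp = compare_models(fits)
    grid = pd.DataFrame(
        {"subspecies": ["melodia"] * 3, "ta": [15.0, 26.0, 37.0], "activity": [4.0] * 3}
    )
    out = model_average_predictions(comp, grid)
    floors = np.min([f.predict(grid)[1] for f in comp.fits], axis=0)
    assert (out["unconditional_se"].to_numpy() >= floors - 1e-12).all()


# --- mixed-model fitting oracles ------------------------------------------


def _spec(response, label):
    return next(s for s in build_model_set(response) if s.label == label)


def test_fit_recovers_known_coefficients_at_tiny_noise():
    """Noise-free generator -> fixed effects recovered to 4 decimals."""
    rng = np.random.default_rng(0)
    birds = [f"b{i}" for i in range(6)]
    rows = []
    for j, b in enumerate(birds):
        for ta in np.arange(15.0, 38.0, 2.0):
            z = (ta - 26.0) / 11.0
            ssp = float(j >= 3)
            act = 4.0 + 0.1 * rng.uniform()
            y = 20.0 + 1.5 * ssp + 3.0 * z - 0.8 * ssp * z + 0.25 * np.sqrt(act)
            rows.append(
                {
                    "bird_id": b,
                    "subspecies": "atlantica" if ssp else "melodia",
                    "ta": ta,
                    "activity": act,
                    "t_base": y + rng.normal(0, 1e-6),
                }
            )
    fit = fit_model(pd.DataFrame(rows), _spec("t_base", "SSP * Ta"))
    assert fit.coefficients["intercept"] == pytest.approx(20.0, abs=1e-4)
    assert fit.coefficients["ssp"] == pytest.approx(1.5, abs=1e-4)
    assert fit.coefficients["ta"] == pytest.approx(3.0, abs=1e-4)
    assert fit.coefficients["ssp:ta"] == pytest.approx(-0.8, abs=1e-4)
    assert fit.coefficients["sqrt_activity"] == pytest.approx(0.25, abs=1e-3)


def test_fit_degenerates_to_ols_without_group_structure():
    """No between-individual variance -> ML fit matches ordinary least squares."""
    rng = np.random.default_rng(1)
    rows = []
    for j in range(8):
        for ta in np.arange(15.0, 38.0, 2.0):
            act = 5.0 + rng.uniform()
            y = 10.0 + 0.4 * ta + rng.normal(0, 0.3)
            rows.append(
                {
                    "bird_id": f"b{j}",
                    "subspecies": "melodia",
                    "ta": ta,
                    "activity": act,
                    "t_bill": y,
                }
            )
    data = pd.DataFrame(rows)
    fit = fit_model(data, _spec("t_bill", "Ta"))
    X = design_matrix(data, ("ta",)).to_numpy()
    beta, *_ = np.linalg.lstsq(X, data["t_bill"].to_numpy(), rcond=None)
    # estimated between-individual variance collapses toward the boundary,
    # and the fixed effects approach the OLS solution
    assert fit.random_intercept_var < 0.05 * fit.residual_var
    assert fit.coefficients.to_numpy() == pytest.approx(beta, abs=0.05)
    ols_fitted = X @ beta
    mixed_fitted = X @ fit.coefficients.to_numpy()
    assert np.sqrt(np.mean((ols_fitted - mixed_fitted) ** 2)) < 0.02


def test_saturated_loglik_dominates_nested(step_data):
    fits = {s.label: fit_model(step_data, s) for s in build_model_set("t_base")}
    top = fits["SSP * Ta + SSP * Ta^2 + SSP * Ta^3"].loglik
    for label, fit in fits.items():
        assert top >= fit.loglik - 1e-4, label


def test_singular_design_raises(step_data):
    data = step_data.copy()
    data["subspecies"] = "melodia"  # constant indicator -> collinear with intercept
    with pytest.raises(ValueError, match="singular"):
        fit_model(data, _spec("t_bill", "SSP"))


def test_mixed_fit_matches_lme4(step_data, tmp_path):
    """Independent route: lme4's ML fit agrees on log-likelihood and effects."""
    assert shutil.which("Rscript"), "Rscript expected on PATH"
    csv = tmp_path / "steps.csv"
    step_data.to_csv(csv, index=False)
    script = tmp_path / "fit.R"
    script.write_text(
        f"""
        suppressMessages(library(lme4))
        d <- read.csv("{csv}")
        d$z <- (d$ta - 26) / 11
        d$ssp <- as.numeric(d$subspecies == "atlantica")
        d$sa <- sqrt(d$activity)
        m <- lmer(t_base ~ ssp * z + sa + (1 | bird_id), data = d, REML = FALSE)
        cat(sprintf("%.8f\\n", as.numeric(logLik(m))))
        cat(sprintf("%.8f\\n", fixef(m)))
        """
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    )
    values = [float(x) for x in out.stdout.split()]
    fit = fit_model(step_data, _spec("t_base", "SSP * Ta"))
    assert fit.loglik == pytest.approx(values[0], abs=1e-4)
    r_coefs = dict(
        zip(["intercept", "ssp", "ta", "sqrt_activity", "ssp:ta"], values[1:])
    )
    for name, value in r_coefs.items():
        assert fit.coefficients[name] == pytest.approx(value, abs=1e-5), name


# --- correlograms ----------------------------------------------------------


def test_correlogram_white_noise_and_lag0(step_data):
    fit = fit_model(step_data, _spec("t_bill", "SSP + Ta"))
    cg = residual_correlogram(fit, step_data)
    assert cg.loc[0, "autocorrelation"] == 1.0
    # independent frame noise: lag 1 is null, and at most one of the six
    # 95% bounds is exceeded (expected false-positive allowance)
    lags = cg[cg["lag"] > 0]
    assert lags.loc[lags["lag"] == 1, "autocorrelation"].iloc[0] < cg.loc[1, "bound"]
    assert (lags["autocorrelation"] >= lags["bound"]).sum() <= 1


def test_correlogram_detects_injected_ar1(step_data):
    rng = np.random.default_rng(5)
    data = step_data.sort_values(["bird_id", "ta"]).reset_index(drop=True).copy()
    parts = []
    for _, g in data.groupby("bird_id"):
        e = np.empty(len(g))
        e[0] = rng.normal(0, 1)
        for i in range(1, len(g)):
            e[i] = 0.8 * e[i - 1] + rng.normal(0, 0.6)
        parts.append(pd.Series(e, index=g.index))
    data["t_bill"] = data["ta"] + 7.0 + pd.concat(parts).sort_index()
    fit = fit_model(data, _spec("t_bill", "Ta"))
    cg = residual_correlogram(fit, data).set_index("lag")
    # strong, clearly detected positive lag-1 correlation (short-series
    # demeaning attenuates the generating 0.8)
    assert cg.loc[1, "autocorrelation"] > 2 * cg.loc[1, "bound"]
    assert cg.loc[1, "autocorrelation"] == max(
        cg.loc[1:, "autocorrelation"]
    )


# --- helpers ----------------------------------------------------------------


def test_pooled_t_matches_scipy_and_bonferroni():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, 9)
    b = rng.normal(0.8, 1, 9)
    p_ref = stats.ttest_ind(a, b, equal_var=True).pvalue
    assert pooled_t_bonferroni(a, b, n_tests=1) == pytest.approx(p_ref)
    assert pooled_t_bonferroni(a, b, n_tests=4) == pytest.approx(min(4 * p_ref, 1.0))
    same = np.array([1.0, 2.0, 3.0])
    assert pooled_t_bonferroni(same, same, n_tests=10) == 1.0


def test_pooled_t_textbook_instance():
    # hand-computed pooled t: means 5 vs 3, s_p^2 = 1, n = 4 each -> t = 2/sqrt(1/2)
    a = np.array([4.0, 5.0, 5.0, 6.0])
    b = np.array([2.0, 3.0, 3.0, 4.0])
    res = stats.ttest_ind(a, b, equal_var=True)
    sp2 = (3 * a.var(ddof=1) + 3 * b.var(ddof=1)) / 6
    t_manual = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 4 + 1 / 4))
    assert res.statistic == pytest.approx(t_manual)
    p_manual = 2 * stats.t.sf(abs(t_manual), df=6)
    assert pooled_t_bonferroni(a, b) == pytest.approx(p_manual)


def test_aggregate_steps(observations):
    agg = aggregate_steps(observations)
    assert len(agg) == 18 * 12
    one = observations[
        (observations["bird_id"] == observations["bird_id"].iloc[0])
        & (observations["ta"] == 15.0)
    ]
    row = agg[(agg["bird_id"] == one["bird_id"].iloc[0]) & (agg["ta"] == 15.0)]
    assert row["t_bill"].iloc[0] == pytest.approx(one["t_bill"].mean())
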