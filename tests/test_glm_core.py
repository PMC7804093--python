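"""Design construction, GLM fits against numerical-MLE oracles, AIC, deviance."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from larvaldelta import (
    AliasingError,
    ModelError,
    ModelSpec,
    aic,
    analysis_of_deviance,
    build_design,
    fit_glm,
    fit_spec,
)


def _design(rows, terms, family="poisson_log", **kw):
    return build_design(rows, ModelSpec("y", tuple(terms), family), **kw)


class TestModelSpec:
    def test_interaction_requires_parents(self):
        with pytest.raises(ModelError, match="parent"):
            ModelSpec("y", ("species", "species:area"), "gamma_log")

    def test_duplicates_and_family(self):
        with pytest.raises(ModelError, match="duplicate"):
            ModelSpec("y", ("a", "a"), "gamma_log")
        with pytest.raises(ModelError, match="family"):
            ModelSpec("y", ("a",), "normal")


class TestBuildDesign:
    def test_intercept_only(self):
        rows = pd.DataFrame({"x": np.arange(10.0)})
        d = _design(rows, ())
        assert d.values.shape == (10, 1)
        assert d.columns == ["Intercept"]

    def test_five_level_factor_treatment_coding(self):
        rows = pd.DataFrame({"species": list("ABCDE") * 2})
        d = _design(rows, ("species",))
        assert d.n_cols == 5  # intercept + 4 indicators
        assert d.reference["species"] == "A"

    def test_interaction_df_three_when_level_missing_from_area(self):
        # five species, two areas, one species observed in one area only:
        # the aliased interaction column is dropped, leaving 3 interaction df
        rows = []
        for area in ("COL", "ISM"):
            for sp in ("Ac", "Gm", "Hc", "Msp", "Oj"):
                if sp == "Oj" and area == "COL":
                    continue
                for _ in range(3):
                    rows.append({"species": sp, "area": area})
        rows = pd.DataFrame(rows)
        d = _design(rows, ("species", "area", "species:area"))
        assert len(d.term_columns["species:area"]) == 3
        with pytest.raises(AliasingError):
            _design(rows, ("species", "area", "species:area"), on_alias="raise")

    def test_unknown_variable(self):
        with pytest.raises(ModelError, match="not present"):
            _design(pd.DataFrame({"x": [1.0, 2.0]}), ("z",))


def _numeric_mle(family, X, y, k_extra=0):
    """Independent oracle: direct numerical maximization of the log-likelihood."""

    def negll(theta):
        beta = theta[: X.shape[1]]
        eta = X @ beta
        if family == "binomial_logit":
            p = 1.0 / (1.0 + np.exp(-eta))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return -np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        mu = np.exp(eta)
        if family == "poisson_log":
            return -np.sum(stats.poisson.logpmf(y, mu))
        if family == "gamma_log":
            a = np.exp(theta[-1])
            return -np.sum(
                a * np.log(a) - special.gammaln(a) - a * np.log(mu)
                + (a - 1) * np.log(y) - a * y / mu
            )
        if family == "negbin_log":
            th = np.exp(theta[-1])
            return -np.sum(stats.nbinom.logpmf(y, th, th / (th + mu)))
        raise AssertionError(family)

    x0 = np.zeros(X.shape[1] + k_extra)
    res = optimize.minimize(negll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000,
                                     "maxfev": 20000})
    assert res.success or res.fun < negll(x0)
    return res.x


@pytest.mark.parametrize("family", ["binomial_logit", "poisson_log", "gamma_log", "negbin_log"])
def test_fit_matches_numerical_mle(family):
    """IRLS coefficients equal direct likelihood maximization (<= 30 rows)."""
    rng = np.random.default_rng(17)
    n = 25
    rows = pd.DataFrame({"x": rng.normal(size=n), "g": rng.choice(["a", "b"], size=n)})
    d = _design(rows, ("x", "g"), family)
    eta = 0.4 + 0.5 * rows["x"].to_numpy() - 0.6 * (rows["g"] == "b").to_numpy()
    if family == "binomial_logit":
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    elif family == "gamma_log":
        y = rng.gamma(shape=2.0, scale=np.exp(eta) / 2.0)
    elif family == "negbin_log":
        th = 1.5  # interior dispersion so theta is identified
        y = rng.negative_binomial(th, th / (th + np.exp(eta))).astype(float)
    else:
        y = rng.poisson(np.exp(eta)).astype(float)
    fit = fit_glm(d, y, family)
    k_extra = 1 if family in ("gamma_log", "negbin_log") else 0
    theta = _numeric_mle(family, d.values, y, k_extra=k_extra)
    np.testing.assert_allclose(fit.params, theta[: d.n_cols], atol=1e-5)
    if k_extra:
        assert fit.dispersion_or_shape == pytest.approx(np.exp(theta[-1]), rel=1e-4)


def test_score_equations_hold_at_optimum():
    """Canonical-link score X'(y − μ) vanishes at the IRLS solution."""
    rng = np.random.default_rng(3)
    rows = pd.DataFrame({"x": rng.normal(size=40)})
    for family, y in (
        ("poisson_log", rng.poisson(3.0, size=40).astype(float)),
        ("binomial_logit", (rng.random(40) < 0.4).astype(float)),
    ):
        d = _design(rows, ("x",), family)
        fit = fit_glm(d, y, family)
        eta = d.values @ fit.params
        mu = np.exp(eta) if family == "poisson_log" else 1 / (1 + np.exp(-eta))
        score = d.values.T @ (y - mu)
        assert np.max(np.abs(score)) < 1e-6


class TestClosedFormFits:
    def test_binomial_intercept_is_logit_proportion(self):
        rows = pd.DataFrame({"z": np.ones(10)})
        d = _design(rows, (), "binomial_logit")
        fit = fit_glm(d, [1, 1, 1, 0, 0, 0, 0, 0, 0, 0], "binomial_logit")
        assert fit.params[0] == pytest.approx(np.log(3 / 7), abs=1e-8)

    def test_gamma_intercept_is_log_mean(self):
        rows = pd.DataFrame({"z": np.ones(3)})
        d = _design(rows, (), "gamma_log")
        fit = fit_glm(d, [2.0, 4.0, 6.0], "gamma_log")
        assert fit.params[0] == pytest.approx(np.log(4.0), abs=1e-8)

    @pytest.mark.parametrize("family", ["gamma_log", "poisson_log"])
    def test_single_factor_reproduces_group_means(self, family):
        rows = pd.DataFrame({"g": ["a"] * 4 + ["b"] * 4})
        y = np.array([1.0, 2, 3, 4, 10, 11, 12, 15])
        fit = fit_spec(rows.assign(y=y), ModelSpec("y", ("g",), family))
        mu = np.exp(fit.design.values @ fit.params)
        assert mu[:4] == pytest.approx(2.5)
        assert mu[4:] == pytest.approx(12.0)


class TestAIC:
    def test_definitional_identity(self):
        rows = pd.DataFrame({"z": np.ones(3)})
        d = _design(rows, (), "poisson_log")
        fit = fit_glm(d, [1.0, 2.0, 3.0], "poisson_log")
        ll_hand = float(stats.poisson.logpmf([1, 2, 3], 2.0).sum())
        assert fit.log_likelihood == pytest.approx(ll_hand, abs=1e-8)
        assert aic(fit) == pytest.approx(2 * 1 - 2 * ll_hand)

    def test_noise_column_changes_aic_by_two_minus_gain(self):
        rng = np.random.default_rng(8)
        rows = pd.DataFrame({"x": rng.normal(size=30)})
        y = rng.poisson(3.0, size=30).astype(float)
        base = fit_glm(_design(rows, (), "poisson_log"), y, "poisson_log")
        noisy = fit_glm(_design(rows, ("x",), "poisson_log"), y, "poisson_log")
        gain = noisy.log_likelihood - base.log_likelihood
        assert aic(noisy) - aic(base) == pytest.approx(2 - 2 * gain, abs=1e-8)

    def test_row_and_column_order_invariance(self):
        rng = np.random.default_rng(9)
        rows = pd.DataFrame({"x": rng.normal(size=30), "g": rng.choice(["a", "b"], 30)})
        y = rng.poisson(2.0, 30).astype(float)
        a = fit_glm(_design(rows, ("x", "g")), y, "poisson_log")
        perm = rng.permutation(30)
        b = fit_glm(_design(rows.iloc[perm].reset_index(drop=True), ("g", "x")),
                    y[perm], "poisson_log")
        assert aic(a) == pytest.approx(aic(b), abs=1e-6)


class TestResponseValidation:
    def test_binomial_requires_01(self):
        d = _design(pd.DataFrame({"z": np.ones(5)}), (), "binomial_logit")
        with pytest.raises(ModelError):
            fit_glm(d, [0, 1, 2, 0, 1], "binomial_logit")

    def test_gamma_requires_positive(self):
        d = _design(pd.DataFrame({"z": np.ones(5)}), (), "gamma_log")
        with pytest.raises(ModelError):
            fit_glm(d, [1.0, 2.0, 0.0, 1.0, 2.0], "gamma_log")

    def test_needs_more_rows_than_columns(self):
        d = _design(pd.DataFrame({"z": np.ones(1)}), (), "poisson_log")
        with pytest.raises(ModelError):
            fit_glm(d, [1.0], "poisson_log")


class TestAnalysisOfDeviance:
    def test_lr_nonnegative_and_rows_complete(self):
        rng = np.random.default_rng(12)
        n = 120
        rows = pd.DataFrame({
            "x": rng.normal(size=n),
            "g": rng.choice(["a", "b", "c"], size=n),
            "h": rng.choice(["u", "v"], size=n),
        })
        y = rng.poisson(np.exp(0.5 + 0.4 * (rows["g"] == "b")), size=n).astype(float)
        tab = analysis_of_deviance(rows.assign(y=y), ModelSpec("y", ("x", "g", "h", "g:h"), "poisson_log"))
        assert list(tab["term"]) == ["x", "g", "h", "g:h"]
        assert (tab["likelihood_ratio"] >= 0).all()
        assert not tab["failed"].any()

    def test_binomial_single_factor_equals_g_statistic(self):
        """LR for a binary factor equals the 2x2 contingency G-statistic."""
        rows = pd.DataFrame({"g": ["a"] * 40 + ["b"] * 40})
        y = np.r_[np.ones(12), np.zeros(28), np.ones(25), np.zeros(15)]
        tab = analysis_of_deviance(rows.assign(y=y), ModelSpec("y", ("g",), "binomial_logit"))
        obs = np.array([[12, 28], [25, 15]], dtype=float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        g_stat = 2.0 * np.sum(obs * np.log(obs / exp))
        assert tab.iloc[0]["likelihood_ratio"] == pytest.approx(g_stat, abs=1e-8)
        assert tab.iloc[0]["df"] == 1

    def test_null_term_type_one_error_rate(self):
        """LR p-values for a truly null factor are approximately uniform:
        rejection rate at alpha = 0.05 lands within ±0.02 over 500 replicates."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n, reps = 150, 500
        for _ in range(reps):
            rows = pd.DataFrame({
                "x": rng.normal(size=n),
                "g": rng.choice(["a", "b"], size=n),
            })
            y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + 0.5 * rows["x"])))).astype(float)
            tab = analysis_of_deviance(rows.assign(y=y), ModelSpec("y", ("x", "g"), "binomial_logit"))
            rejections += tab.set_index("term").loc["g", "p_value"] < 0.05
        assert abs(rejections / reps - 0.05) <= 0.02
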