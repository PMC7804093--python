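"""Two-part delta model: fits, the product estimator, prediction."""

import numpy as np
import pandas as pd
import pytest

from larvaldelta import (
    DegenerateDataError,
    ModelSpec,
    aic,
    combine_estimate,
    delta_aic,
    fit_delta,
    predict_cells,
)
from larvaldelta.pipeline import build_model_frame
from larvaldelta.synthetic import generate_dataset
from tests.conftest import recovery_config


def _specs(terms, family="gamma_log"):
    return (ModelSpec("response", tuple(terms), "binomial_logit"),
            ModelSpec("response", tuple(terms), family))


class TestFitDelta:
    def test_intercept_only_sample_statistics(self):
        rows = pd.DataFrame({"z": np.ones(6)})
        y = [0.0, 0, 0, 0, 2.0, 6.0]
        m = fit_delta(rows, y, *_specs(()))
        p = 1 / (1 + np.exp(-m.presence_fit.params[0]))
        assert p == pytest.approx(2 / 6, abs=1e-8)
        assert np.exp(m.positive_fit.params[0]) == pytest.approx(4.0, abs=1e-6)
        assert (m.n_total, m.n_positive) == (6, 2)

    @pytest.mark.parametrize("y", [[0.0] * 6, [1.0, 2, 3, 4, 5, 6]])
    def test_degenerate_response(self, y):
        rows = pd.DataFrame({"z": np.ones(6)})
        with pytest.raises(DegenerateDataError):
            fit_delta(rows, y, *_specs(()))

    def test_sub_fits_independent(self):
        ds, _ = generate_dataset(recovery_config(1))
        fr = build_model_frame(ds)
        terms = ("abundance", "season", "species", "area")
        m1 = fit_delta(fr, fr["response"], *_specs(terms))
        # permute positive rows (by permuting all rows): positive fit unchanged
        perm = np.random.default_rng(0).permutation(len(fr))
        fr2 = fr.iloc[perm].reset_index(drop=True)
        m2 = fit_delta(fr2, fr2["response"], *_specs(terms))
        np.testing.assert_allclose(
            sorted(m1.positive_fit.params), sorted(m2.positive_fit.params), atol=1e-8
        )
        # refitting presence with different terms leaves positive coefs alone
        m3 = fit_delta(fr, fr["response"],
                       ModelSpec("response", ("species",), "binomial_logit"),
                       ModelSpec("response", terms, "gamma_log"))
        np.testing.assert_allclose(m1.positive_fit.params, m3.positive_fit.params, atol=0)


class TestCombineEstimate:
    def test_certain_presence(self):
        e = combine_estimate(1.0, 0.0, 7.5, 2.25)
        assert e.dc_hat == 7.5 and e.var_dc == 2.25

    def test_stated_arithmetic(self):
        e = combine_estimate(0.5, 0.01, 10.0, 4.0)
        assert e.dc_hat == pytest.approx(5.0)
        assert e.var_dc == pytest.approx(0.25 * 4 + 0.01 * 100)  # = 2.0

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            combine_estimate(0.5, -0.1, 1.0, 1.0)

    def test_exact_identities_on_random_inputs(self):
        rng = np.random.default_rng(4)
        for _ in range(200):
            p, vp, dp, vdp = rng.random(), rng.random(), rng.random() * 10 + 0.1, rng.random()
            e = combine_estimate(p, vp, dp, vdp)
            assert e.dc_hat == p * dp  # machine-precision identity
            assert e.var_dc == p ** 2 * vdp + vp * dp ** 2

    def test_variance_matches_monte_carlo_product(self):
        """In the small-CV regime the stated combination approximates the
        variance of the product of independent presence and positive parts."""
        rng = np.random.default_rng(99)
        p, vp, dp, vdp = 0.6, 0.001, 20.0, 1.0
        draws = rng.normal(p, np.sqrt(vp), 100_000) * rng.normal(dp, np.sqrt(vdp), 100_000)
        mc = draws.var()
        e = combine_estimate(p, vp, dp, vdp)
        assert e.var_dc == pytest.approx(mc, rel=0.10)


class TestPrediction:
    def test_intercept_only_identical_cells(self):
        rows = pd.DataFrame({"z": np.ones(8)})
        y = [0.0, 0, 0, 1.5, 2.5, 3.0, 0, 4.0]
        m = fit_delta(rows, y, *_specs(()))
        cells = pd.DataFrame({"z": [1.0, 1.0, 1.0]})
        preds = predict_cells(m, cells)
        assert preds["dc_hat"].nunique() == 1
        assert preds["estimable"].all()

    def test_saturated_one_factor_oracle(self):
        """Per-level dc equals (share of positive cells) × (positive mean)."""
        rows = pd.DataFrame({"g": ["a"] * 10 + ["b"] * 10})
        y = np.r_[np.zeros(6), [2.0, 2, 5, 7], np.zeros(5), [1.0, 3, 3, 3, 10]]
        m = fit_delta(rows, y, *_specs(("g",)))
        preds = predict_cells(m, pd.DataFrame({"g": ["a", "b"]}))
        ya, yb = y[:10], y[10:]
        assert preds.iloc[0]["dc_hat"] == pytest.approx(
            (ya > 0).mean() * ya[ya > 0].mean(), abs=1e-6)
        assert preds.iloc[1]["dc_hat"] == pytest.approx(
            (yb > 0).mean() * yb[yb > 0].mean(), abs=1e-6)

    def test_unseen_positive_level_not_estimable(self):
        rows = pd.DataFrame({"g": ["a"] * 8 + ["b"] * 8})
        y = np.r_[np.zeros(4), [2.0, 3, 4, 5], np.zeros(8)]  # b never positive
        m = fit_delta(rows, y, *_specs(("g",)))
        preds = predict_cells(m, pd.DataFrame({"g": ["a", "b"]}))
        assert bool(preds.iloc[0]["estimable"])
        assert not bool(preds.iloc[1]["estimable"])
        assert np.isnan(preds.iloc[1]["dc_hat"])

    def test_identities_hold_on_model_predictions(self):
        ds, _ = generate_dataset(recovery_config(2))
        fr = build_model_frame(ds)
        m = fit_delta(fr, fr["response"], *_specs(("species", "season")))
        grid = pd.DataFrame(
            [{"species": s, "season": se} for s in ("Ac", "Gm", "Hc")
             for se in ("autumn_winter", "spring_summer")]
        )
        preds = predict_cells(m, grid)
        np.testing.assert_array_equal(
            preds["dc_hat"].to_numpy(), (preds["p_hat"] * preds["dp_hat"]).to_numpy()
        )
        np.testing.assert_allclose(
            preds["se_dc"].to_numpy() ** 2,
            (preds["p_hat"] ** 2 * preds["se_dp"] ** 2
             + preds["se_p"] ** 2 * preds["dp_hat"] ** 2).to_numpy(),
            rtol=1e-12,  # exact up to the sqrt/square round-trip
        )

    def test_monotone_in_presence_covariate(self):
        rng = np.random.default_rng(6)
        n = 200
        rows = pd.DataFrame({"x": rng.normal(size=n)})
        eta = -0.3 + 1.2 * rows["x"].to_numpy()
        pres = rng.random(n) < 1 / (1 + np.exp(-eta))
        y = np.where(pres, rng.gamma(2.0, 5.0, size=n), 0.0)
        if not (y > 0).any() or (y > 0).all():
            pytest.skip("degenerate draw")
        m = fit_delta(rows, y, ModelSpec("response", ("x",), "binomial_logit"),
                      ModelSpec("response", (), "gamma_log"))
        xs = pd.DataFrame({"x": np.linspace(-2, 2, 9)})
        dc = predict_cells(m, xs)["dc_hat"].to_numpy()
        assert np.all(np.diff(dc) >= -1e-12)


class TestDeltaAIC:
    def test_additivity_and_family_swap(self):
        ds, _ = generate_dataset(recovery_config(3))
        fr = build_model_frame(ds)
        terms = ("species", "season")
        mg = fit_delta(fr, fr["response"], *_specs(terms, "gamma_log"))
        mp = fit_delta(fr, fr["response"], *_specs(terms, "poisson_log"))
        assert delta_aic(mg) == pytest.approx(aic(mg.presence_fit) + aic(mg.positive_fit))
        assert delta_aic(mp) - delta_aic(mg) == pytest.approx(
            aic(mp.positive_fit) - aic(mg.positive_fit)
        )
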