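"""Relative-use predictions, rescaling, marginal profiles, predictive surfaces."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from nbrspf import (
    NegativeBinomialRSPF,
    OutOfRangeWarning,
    UnitTable,
    bootstrap_by_animal,
    fit_nb2,
    marginal_profile,
    predict_units,
    prediction_surface,
    simulate_counts,
)
from nbrspf.bootstrap import BootstrapResults
from nbrspf.model import RSPFResults
from nbrspf.simulate import elk_like_spec, make_systematic_units, simulate_locations

from conftest import make_covariate_units


def full_rank_exog(cov_names, cov_rows, n=12, seed=0):
    """Random covariate rows spanning (and including) the given anchor rows."""
    rng = np.random.default_rng(seed)
    anchors = pd.DataFrame(cov_rows, columns=list(cov_names), dtype=float)
    lo, hi = anchors.min(), anchors.max()
    exog = pd.DataFrame(
        {c: rng.uniform(lo[c], hi[c] if hi[c] > lo[c] else lo[c] + 1.0, n) for c in cov_names}
    )
    exog.iloc[: len(anchors)] = anchors.to_numpy()
    return exog


def results_with_coefficients(beta, cov_names, cov_rows):
    """A results object carrying chosen coefficients over given covariates."""
    exog = full_rank_exog(cov_names, cov_rows)
    model = NegativeBinomialRSPF(np.ones(len(exog), dtype=int), exog)
    k = len(beta)
    return RSPFResults(
        model, np.asarray(beta, float), 1.0, np.ones(len(exog)), 0.0, np.eye(k), 1
    )


class TestPredict:
    def test_zero_covariates_give_exp_intercept(self):
        res = results_with_coefficients([1.3, 0.7], ["x"], [[0.0], [1.0]])
        pred = res.predict(pd.DataFrame({"x": [0.0]}))
        assert pred[0] == pytest.approx(np.exp(1.3), rel=1e-12)

    def test_published_elk_coefficients_hand_evaluation(self):
        # beta0 -8.025; road 0.545/km, slope 0.002/%, edge -0.355/km, soil 0.022/cm
        beta = [-8.025, 0.545, 0.002, -0.355, 0.022]
        names = ["road", "slope", "edge", "soil"]
        res = results_with_coefficients(
            beta, names, [[0, 0, 0, 0], [2, 50, 1.2, 185]]
        )
        point = pd.DataFrame({"road": [1.0], "slope": [20.0], "edge": [0.5], "soil": [100.0]})
        pred = res.predict(point)
        by_hand = np.exp(-8.025 + 0.545 * 1 + 0.002 * 20 - 0.355 * 0.5 + 0.022 * 100)
        assert pred[0] == pytest.approx(by_hand, rel=1e-12)
        assert pred[0] == pytest.approx(4.44e-3, abs=5e-5)

    def test_identical_covariates_identical_predictions(self):
        res = results_with_coefficients([0.5, 1.0], ["x"], [[0.0], [1.0]])
        pred = res.predict(pd.DataFrame({"x": [0.4, 0.4, 0.9]}))
        assert pred[0] == pred[1] != pred[2]

    def test_prediction_per_unit_independent_of_order(self):
        units = make_covariate_units(50, seed=4)
        counted = simulate_counts(units, {"const": 1.0, "x": 1.0}, 0.8, 1.0, seed=5)
        res = fit_nb2(counted)
        surf = predict_units(res, counted)
        shuffled = UnitTable(
            counted.frame.sample(frac=1.0, random_state=3).reset_index(drop=True)
        )
        surf2 = predict_units(res, shuffled)
        merged = surf.frame.merge(surf2.frame, on="unit_id", suffixes=("_a", "_b"))
        np.testing.assert_allclose(merged["predicted_a"], merged["predicted_b"])

    def test_rescale_modes(self):
        res = results_with_coefficients([0.0, 1.0], ["x"], [[0.0], [1.0]])
        grid = pd.DataFrame({"x": np.linspace(0, 1, 11)})
        raw = res.predict(grid)
        assert res.predict(grid, rescale="max1").max() == pytest.approx(1.0)
        s = res.predict(grid, rescale="unit_sum")
        assert s.sum() == pytest.approx(1.0, abs=1e-12)
        assert (s > 0).all()
        np.testing.assert_allclose(s, raw / raw.sum())
        with pytest.raises(ValueError, match="rescale"):
            res.predict(grid, rescale="bogus")

    def test_relative_scale_excludes_offset_and_count_scale_restores_it(self):
        units = make_covariate_units(300, seed=8)
        counted = simulate_counts(units, {"const": -5.0, "x": 1.0}, 0.8, 1000.0, seed=9)
        res = fit_nb2(counted, offset_total=1000.0)
        rel = res.predict(counted.frame)
        cnt = res.predict(counted.frame, scale="count")
        np.testing.assert_allclose(cnt, rel * 1000.0)
        assert (rel > 0).all() and (rel < 1).all()  # relative frequencies

    def test_radius_mismatch_rejected(self):
        units = make_covariate_units(60, seed=1, radius=100.0)
        counted = simulate_counts(units, {"const": 1.0, "x": 1.0}, 0.8, 1.0, seed=2)
        res = fit_nb2(counted)
        other = UnitTable(counted.frame.assign(radius=250.0))
        with pytest.raises(ValueError, match="radius"):
            predict_units(res, other)

    def test_unknown_covariate_rejected(self):
        res = results_with_coefficients([0.0, 1.0], ["x"], [[0.0], [1.0]])
        with pytest.raises(ValueError, match="unknown covariate"):
            res.predict(pd.DataFrame({"y": [1.0]}))

    def test_out_of_range_warns_but_predicts(self):
        res = results_with_coefficients([0.0, 1.0], ["x"], [[0.0], [1.0]])
        with pytest.warns(OutOfRangeWarning):
            pred = res.predict(pd.DataFrame({"x": [2.0]}))
        assert np.isfinite(pred).all()

    def test_recentring_a_covariate_leaves_predictions_invariant(self):
        units = make_covariate_units(400, seed=12)
        counted = simulate_counts(units, {"const": 1.0, "x": 1.5}, 0.5, 1.0, seed=13)
        res1 = fit_nb2(counted)
        shifted = UnitTable(counted.frame.assign(x=counted.frame["x"] - 0.5))
        res2 = fit_nb2(shifted)
        p1 = res1.predict(counted.frame, warn_out_of_range=False)
        p2 = res2.predict(shifted.frame, warn_out_of_range=False)
        np.testing.assert_allclose(p1, p2, rtol=1e-6)


class TestPredictionSurface:
    def test_uniform_covariates_give_constant_surface(self):
        res = results_with_coefficients([0.2, 0.5], ["x"], [[0.0], [1.0]])
        grid = pd.DataFrame({"center_x": np.arange(9.0), "center_y": 0.0, "x": 0.5})
        surf = prediction_surface(res, grid, rescale="unit_sum")
        np.testing.assert_allclose(surf.predicted, 1.0 / 9.0)

    def test_max1_rescale_puts_argmax_at_one(self):
        res = results_with_coefficients([0.2, 0.5], ["x"], [[0.0], [1.0]])
        grid = pd.DataFrame({"center_x": np.arange(5.0), "center_y": 0.0,
                             "x": np.linspace(0, 1, 5)})
        surf = prediction_surface(res, grid, rescale="max1")
        assert surf.predicted.max() == 1.0

    def test_surface_ranks_true_intensity(self):
        units = make_covariate_units(500, seed=20)
        true = {"const": 1.0, "x": 1.5}
        counted = simulate_counts(units, true, 0.5, 1.0, seed=21)
        res = fit_nb2(counted)
        pred = res.predict(counted.frame)
        mu_true = np.exp(true["const"] + true["x"] * counted.covariates(["x"])[:, 0])
        assert spearmanr(pred, mu_true).statistic >= 0.9


def synthetic_bootstrap(replicates, cov_rows, cov_names):
    """BootstrapResults with hand-chosen replicate coefficients (synthetic)."""
    exog = full_rank_exog(cov_names, cov_rows)
    n = len(exog)
    model = NegativeBinomialRSPF(np.ones(n, dtype=int), exog)
    k = replicates.shape[1]
    point = RSPFResults(model, replicates.mean(axis=0), 1.0, np.ones(n), 0.0, np.eye(k), 1)
    reps = pd.DataFrame(replicates, columns=model.exog_names)
    return BootstrapResults(
        replicates=reps,
        theta_reps=np.ones(len(reps)),
        point_fit=point,
        se=reps.std(),
        ci_lower=reps.quantile(0.05),
        ci_upper=reps.quantile(0.95),
        level=0.90,
        B=len(reps),
        n_failed=0,
    )


class TestMarginalProfile:
    def test_zero_coefficient_gives_flat_profile(self):
        rng = np.random.default_rng(0)
        reps = np.column_stack([rng.normal(0, 0.1, 40), rng.normal(1, 0.1, 40), np.zeros(40)])
        boot = synthetic_bootstrap(reps, [[0.0, 0.0], [1.0, 1.0]], ["x", "z"])
        prof = marginal_profile(boot, "z", n_grid=15)
        assert np.allclose(prof.median, prof.median[0])

    def test_monotone_positive_coefficient_increases_to_scaled_max(self):
        rng = np.random.default_rng(1)
        reps = np.column_stack([rng.normal(0, 0.1, 40), np.abs(rng.normal(1.0, 0.2, 40))])
        boot = synthetic_bootstrap(reps, [[0.0], [1.0]], ["x"])
        prof = marginal_profile(boot, "x", n_grid=20)
        assert (np.diff(prof.median) > 0).all()
        # all three curves share one scale and the overall maximum is exactly 1
        assert max(prof.median.max(), prof.lower.max(), prof.upper.max()) == pytest.approx(1.0)
        assert (prof.lower <= prof.median).all() and (prof.median <= prof.upper).all()

    def test_grid_spans_observed_range_only(self):
        rng = np.random.default_rng(2)
        reps = np.column_stack([rng.normal(0, 0.1, 30), rng.normal(1, 0.1, 30)])
        boot = synthetic_bootstrap(reps, [[0.2], [0.8]], ["x"])
        prof = marginal_profile(boot, "x", n_grid=10)
        assert prof.grid.min() == pytest.approx(0.2)
        assert prof.grid.max() == pytest.approx(0.8)

    def test_unknown_covariate_rejected(self):
        rng = np.random.default_rng(3)
        reps = np.column_stack([rng.normal(0, 0.1, 30), rng.normal(1, 0.1, 30)])
        boot = synthetic_bootstrap(reps, [[0.0], [1.0]], ["x"])
        with pytest.raises(ValueError, match="covariate"):
            marginal_profile(boot, "nope")

    def test_envelope_contains_true_response_shape(self):
        """End-to-end on the default synthetic herd: the bootstrap envelope
        should contain the known response curve (up to its free scaling) at
        most grid points, pooled over the four modeled covariates."""
        spec = elk_like_spec()
        units = make_systematic_units(spec, seed=5)
        locs, _ = simulate_locations(spec, seed=1005)
        boot = bootstrap_by_animal(locs, units, B=200, seed=2025)
        inside = []
        for cov in spec.fit_covariates:
            prof = boot.marginal_profile(cov, n_grid=25)
            shape = np.exp(spec.beta[cov] * prof.grid)
            scale = np.exp(np.mean(np.log(prof.median) - np.log(shape)))
            truth = scale * shape
            inside.extend(((prof.lower <= truth) & (truth <= prof.upper)).tolist())
        assert np.mean(inside) >= 0.85
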