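import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from enmecotype.features import FeatureBuilder
from enmecotype.maxent import (MaxentError, MaxentModel, fit_maxent,
                               fit_on_tables, gain, predict, predict_rows)


def brute_force_objective(bg, p_mean, betas):
    """Generic convex optimizer on the same L1 objective (split positive/negative)."""
    n_f = bg.shape[1]

    def obj(uv):
        lam = uv[:n_f] - uv[n_f:]
        eta = bg @ lam
        c = eta.max()
        logz = c + np.log(np.exp(eta - c).sum())
        return -p_mean @ lam + logz + betas @ (uv[:n_f] + uv[n_f:])

    res = minimize(obj, np.zeros(2 * n_f), bounds=[(0, None)] * (2 * n_f),
                   method="L-BFGS-B",
                   options=dict(ftol=1e-15, gtol=1e-12, maxiter=10000))
    return res.fun


class TestFit:
    def test_objective_matches_generic_convex_optimizer(self, toy_maxent):
        m = toy_maxent["model"]
        oracle = brute_force_objective(
            toy_maxent["bg"], toy_maxent["pres"].mean(0), m.betas
        )
        assert m.objective == pytest.approx(oracle, abs=1e-6)

    def test_kkt_conditions_at_optimum(self, toy_maxent):
        m, bg = toy_maxent["model"], toy_maxent["bg"]
        w = np.exp(bg @ m.lambdas)
        w /= w.sum()
        model_mean = w @ bg
        for j in range(bg.shape[1]):
            g = m.presence_mean[j] - model_mean[j]
            if m.lambdas[j] == 0:
                assert abs(g) <= m.betas[j] + 1e-6
            else:
                assert g == pytest.approx(m.betas[j] * np.sign(m.lambdas[j]),
                                          abs=1e-5)

    def test_huge_beta_multiplier_shrinks_to_uniform(self, toy_maxent):
        m = fit_maxent(toy_maxent["x"], toy_maxent["pidx"], bm=1e9)
        assert np.all(m.lambdas == 0)
        assert m.entropy == pytest.approx(np.log(m.n_background))

    def test_total_l1_norm_non_increasing_in_bm(self, toy_maxent):
        norms = [
            np.abs(fit_maxent(toy_maxent["x"], toy_maxent["pidx"], bm=bm).lambdas).sum()
            for bm in (0.5, 1.0, 2.0, 4.0, 8.0)
        ]
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))

    def test_objective_non_increasing_with_more_sweeps(self, toy_maxent):
        objs = [
            fit_maxent(toy_maxent["x"], toy_maxent["pidx"], bm=1.0,
                       max_sweeps=k, tol=0.0).objective
            for k in (1, 2, 3, 5, 10)
        ]
        assert all(a >= b - 1e-12 for a, b in zip(objs, objs[1:]))

    def test_accepted_updates_always_improve(self, toy_maxent):
        assert all(delta > 0 for _, delta in toy_maxent["model"].trace)

    def test_no_presence_rows_rejected(self, toy_maxent):
        with pytest.raises(MaxentError):
            fit_maxent(toy_maxent["x"], np.array([], dtype=int))

    def test_non_finite_features_rejected(self, toy_maxent):
        x = toy_maxent["x"].copy()
        x[0, 0] = np.nan
        with pytest.raises(MaxentError):
            fit_maxent(x, toy_maxent["pidx"])

    def test_serialization_round_trip(self, tmp_path, toy_maxent):
        rng = np.random.default_rng(1)
        bg = pd.DataFrame({"a": rng.uniform(0, 1, 30), "b": rng.uniform(0, 1, 30)})
        pres = bg.iloc[:5]
        m = fit_on_tables(bg, pres, {"a": "continuous", "b": "continuous"},
                          fc_set=("L", "Q"), bm=1.0)
        m.save(tmp_path / "m.json")
        m2 = MaxentModel.load(tmp_path / "m.json")
        np.testing.assert_array_equal(m.lambdas, m2.lambdas)
        assert m2.log_z == m.log_z


class TestPredict:
    @pytest.fixture
    def null_model_and_stack(self, small_stack):
        bg = small_stack.background_table().drop(columns=["row", "col"])
        builder = FeatureBuilder(bg, {n: "continuous" for n in small_stack.names},
                                 fc_set=("L",))
        f_bg, _ = builder.transform(bg)
        features = np.vstack([f_bg, f_bg[:1]])
        model = fit_maxent(features, np.array([len(f_bg)]), bm=1e9,
                           builder=builder)
        return model, small_stack

    def test_null_model_is_uniform_with_logistic_half(self, null_model_and_stack):
        model, stack = null_model_and_stack
        surf = predict(model, stack)
        n_valid = stack.mask.sum()
        np.testing.assert_allclose(surf.raw[stack.mask], 1.0 / n_valid)
        np.testing.assert_allclose(surf.logistic[stack.mask], 0.5)

    def test_raw_sums_to_one(self, default_scenario):
        stack = default_scenario.stack.subset(["temp_max", "temp_wet"])
        bg = stack.background_table().drop(columns=["row", "col"])
        from enmecotype.raster import extract_at

        rows = extract_at(stack, default_scenario.occurrences.lonlat())
        pres = rows[rows["status"] == "ok"][stack.names]
        model = fit_on_tables(bg, pres, {n: "continuous" for n in stack.names},
                              fc_set=("H",), bm=1.0, n_knots=5)
        surf = predict(model, stack)
        assert np.nansum(surf.raw) == pytest.approx(1.0, abs=1e-9)
        # cell at raw = e^-H has logistic exactly one half
        np.testing.assert_allclose(
            surf.logistic[stack.mask],
            1 / (1 + np.exp(-(np.log(surf.raw[stack.mask]) + model.entropy))),
            atol=1e-12,
        )

    def test_outputs_are_rank_consistent(self, default_scenario):
        stack = default_scenario.stack.subset(["temp_max"])
        bg = stack.background_table().drop(columns=["row", "col"])
        from enmecotype.raster import extract_at

        rows = extract_at(stack, default_scenario.occurrences.lonlat())
        pres = rows[rows["status"] == "ok"][stack.names]
        model = fit_on_tables(bg, pres, {"temp_max": "continuous"},
                              fc_set=("H",), bm=1.0, n_knots=5)
        surf = predict(model, stack)
        raw = surf.raw[stack.mask]
        for other in (surf.logistic[stack.mask], surf.cumulative[stack.mask]):
            order = np.argsort(raw, kind="stable")
            assert np.all(np.diff(other[order]) >= -1e-12)

    def test_max_raw_cell_has_cumulative_100(self, null_model_and_stack):
        model, stack = null_model_and_stack
        surf = predict(model, stack)
        cum = surf.cumulative[stack.mask]
        assert cum.max() == pytest.approx(100.0)


class TestGain:
    def test_null_model_gain_is_zero(self, toy_maxent):
        m = fit_maxent(toy_maxent["x"], toy_maxent["pidx"], bm=1e9)
        g, _ = gain(m, toy_maxent["pres"])
        assert g == pytest.approx(0.0, abs=1e-12)

    def test_regularized_gain_never_exceeds_gain(self, toy_maxent):
        m = toy_maxent["model"]
        g, rg = gain(m, toy_maxent["pres"])
        assert rg <= g + 1e-12

    def test_hand_computed_gain_on_four_cell_model(self):
        # 4 background cells, 1 feature, lambda fixed at 1 by construction
        bg = np.array([[0.0], [0.25], [0.5], [1.0]])
        pres = np.array([[1.0]])
        lam = np.array([1.0])
        log_z = np.log(np.exp(bg @ lam).sum())
        model = MaxentModel(
            builder=None, lambdas=lam, betas=np.array([0.0]),
            log_z=float(log_z), entropy=0.0, bm=1.0, n_presence=1,
            n_background=4, objective=0.0, presence_mean=pres.mean(0),
        )
        g, rg = gain(model, pres)
        # direct summation oracle
        expected = (1.0 - np.log(np.exp([0, 0.25, 0.5, 1.0]).sum())) + np.log(4)
        assert g == pytest.approx(expected, abs=1e-12)
        assert rg == pytest.approx(expected, abs=1e-12)
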