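"""Super-learner stacking: tuning, leakage-safe OOF predictions, NNLS
meta-learner (with brute-force oracles), grid prediction, importance."""

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import airstack.ensemble as ens
from airstack.ensemble import (BaseLearnerSpec, EnsembleWeights, fit_final,
                               fit_meta_nnls, oof_predictions, predict_grid,
                               tune_learner, variable_importance)
from airstack.evaluation import make_folds
from airstack.grids import GridDomain


def nnls_exact_oracle(F, y):
    """Exact NNLS optimum by enumerating every possible active support and
    solving its unconstrained least squares (the optimum is the best
    feasible candidate among them).  Independent of scipy's solver."""
    n, m = F.shape
    best = float(np.sum(y ** 2))  # w = 0
    for r in range(1, m + 1):
        for sub in itertools.combinations(range(m), r):
            Fs = F[:, sub]
            w, *_ = np.linalg.lstsq(Fs, y, rcond=None)
            if (w >= -1e-12).all():
                resid = y - Fs @ np.clip(w, 0, None)
                best = min(best, float(resid @ resid))
    return best


def nnls_grid_oracle(F, y, final_step=1e-3, w_max=3.0):
    """Cyclic coordinate search over a nonnegative grid, refined down to
    ``final_step``; returns the best objective found."""
    m = F.shape[1]
    w = np.zeros(m)

    def obj(w):
        r = y - F @ w
        return float(r @ r)

    for step in (0.1, 0.01, final_step):
        improved = True
        while improved:
            improved = False
            for j in range(m):
                grid = np.arange(0.0, w_max + step, step)
                r_other = y - F @ w + F[:, j] * w[j]
                vals = np.sum((r_other[:, None] - F[:, [j]] * grid[None, :]) ** 2, axis=0)
                k = int(np.argmin(vals))
                if grid[k] != w[j]:
                    w[j] = grid[k]
                    improved = True
    return obj(w)


def _panel(rng, n_mon=15, n_days=30, n_feat=5):
    rows = n_mon * n_days
    X = pd.DataFrame(rng.normal(size=(rows, n_feat)),
                     columns=[f"f{i}" for i in range(n_feat)])
    beta = rng.normal(size=n_feat)
    groups = np.repeat([f"M{i}" for i in range(n_mon)], n_days)
    mon_effect = np.repeat(rng.normal(scale=2.0, size=n_mon), n_days)
    y = 10 + X.to_numpy() @ beta + mon_effect + rng.normal(scale=0.5, size=rows)
    return X, y, groups


class TestNnlsMetaLearner:
    def test_exact_fit_single_learner(self, rng):
        y = rng.uniform(1, 30, size=40)
        F = np.column_stack([y, rng.normal(size=40), rng.normal(size=40)])
        w = fit_meta_nnls(F, y)
        np.testing.assert_allclose(w.weights, [1.0, 0.0, 0.0], atol=1e-10)
        assert w.rss == pytest.approx(0.0, abs=1e-16)

    def test_anticorrelated_learner_gets_zero_weight(self, rng):
        y = rng.uniform(1, 30, size=50)
        F = np.column_stack([y + rng.normal(scale=0.5, size=50), -y])
        w = fit_meta_nnls(F, y)
        assert w.weights[1] == 0.0
        assert w.rss <= nnls_grid_oracle(F, y) + 1e-6

    def test_matches_bruteforce_oracles(self, rng):
        """Objective equals the support-enumeration optimum to 1e-6 and is
        never beaten by a dense nonnegative grid search (step 1e-3)."""
        for _ in range(25):
            F = np.column_stack([
                rng.normal(loc=10, scale=3, size=50) for _ in range(3)])
            y = 0.5 * F[:, 0] + 0.4 * F[:, 1] + rng.normal(scale=0.5, size=50)
            w = fit_meta_nnls(F, y)
            exact = nnls_exact_oracle(F, y)
            assert w.rss == pytest.approx(exact, abs=1e-6)
            assert w.rss <= nnls_grid_oracle(F, y) + 1e-6

    def test_dominates_every_single_learner(self, rng):
        for _ in range(20):
            F = rng.normal(loc=15, scale=4, size=(60, 4))
            y = F @ rng.uniform(0, 0.5, size=4) + rng.normal(size=60)
            w = fit_meta_nnls(F, y)
            single = [float(np.sum((y - F[:, j]) ** 2)) for j in range(4)]
            assert w.rss <= min(single) + 1e-9

    def test_all_zero_predictions_warn(self):
        with pytest.warns(UserWarning, match="all-zero"):
            w = fit_meta_nnls(np.zeros((10, 2)), np.ones(10))
        np.testing.assert_array_equal(w.weights, 0.0)

    def test_nonnegativity_enforced(self):
        with pytest.raises(ValueError, match="non-negative"):
            EnsembleWeights(("a", "b"), np.array([0.5, -0.1]), 0.0)


class TestTuning:
    def test_budget_one_returns_single_draw(self, rng):
        X, y, g = _panel(rng)
        spec = BaseLearnerSpec("ridge", seed=0)
        tuned, log = tune_learner(spec, X, y, g, budget=1)
        assert len(log) == 1
        assert tuned.hyperparameters == log.loc[0, "params"]

    def test_argmin_property(self, rng):
        X, y, g = _panel(rng)
        tuned, log = tune_learner(BaseLearnerSpec("lasso", seed=1), X, y, g, budget=8)
        best = log.loc[log["cv_rmse"].idxmin()]
        assert tuned.hyperparameters == best["params"]
        assert best["cv_rmse"] == log["cv_rmse"].min()

    def test_search_log_deterministic(self, rng):
        X, y, g = _panel(rng)
        spec = BaseLearnerSpec("ridge", seed=5)
        _, log1 = tune_learner(spec, X, y, g, budget=5)
        _, log2 = tune_learner(spec, X, y, g, budget=5)
        pd.testing.assert_frame_equal(log1, log2)

    def test_zero_budget_rejected(self, rng):
        X, y, g = _panel(rng)
        with pytest.raises(ValueError):
            tune_learner(BaseLearnerSpec("ridge"), X, y, g, budget=0)

    def test_rf_bypasses_tuning(self, rng):
        X, y, g = _panel(rng)
        spec = BaseLearnerSpec("RF", seed=2)
        tuned, log = tune_learner(spec, X, y, g, budget=10)
        assert tuned is spec
        assert "bypassed" in log.loc[0, "note"]


class TestOofPredictions:
    def test_each_learner_fitted_once_per_fold(self, rng, monkeypatch):
        X, y, g = _panel(rng, n_mon=12, n_days=10)
        folds = make_folds(list(pd.unique(g)), n_folds=6, seed=0)
        calls = []
        orig = ens._fit
        monkeypatch.setattr(ens, "_fit", lambda *a: calls.append(1) or orig(*a))
        specs = [BaseLearnerSpec("ridge"), BaseLearnerSpec("lasso")]
        out = oof_predictions(specs, X, y, g, folds)
        assert len(calls) == 2 * 6
        assert {"ridge", "lasso", "fold"} <= set(out.columns)
        assert out.notna().all().all()

    def test_fold_column_matches_assignment(self, rng):
        X, y, g = _panel(rng, n_mon=12, n_days=6)
        folds = make_folds(list(pd.unique(g)), n_folds=4, seed=1)
        out = oof_predictions([BaseLearnerSpec("ridge")], X, y, g, folds)
        np.testing.assert_array_equal(out["fold"].to_numpy(), folds.fold_of(g))

    def test_unassigned_block_rejected(self, rng):
        X, y, g = _panel(rng, n_mon=12, n_days=4)
        folds = make_folds(list(pd.unique(g))[:-1] + ["other"], n_folds=4, seed=0)
        with pytest.raises(ValueError, match="without a fold"):
            oof_predictions([BaseLearnerSpec("ridge")], X, y, g, folds)

    def test_leakage_probe(self, rng):
        """Replacing one monitor's series with a unique constant leaves the
        model that scores its fold untouched (it never saw that fold), so
        its own OOF predictions are unchanged — and do not collapse to
        the constant."""
        X, y, g = _panel(rng, n_mon=12, n_days=20)
        folds = make_folds(list(pd.unique(g)), n_folds=6, seed=3)
        spec = BaseLearnerSpec("LGBM", hyperparameters={"n_estimators": 50}, seed=0)
        base = oof_predictions([spec], X, y, g, folds)

        victim = "M3"
        y2 = np.where(g == victim, 777.0, y)
        pert = oof_predictions([spec], X, y2, g, folds)

        vfold = folds.assignment[victim]
        in_vfold = base["fold"].to_numpy() == vfold
        np.testing.assert_array_equal(base.loc[in_vfold, "LGBM"].to_numpy(),
                                      pert.loc[in_vfold, "LGBM"].to_numpy())
        own = pert.loc[np.asarray(g) == victim, "LGBM"]
        assert np.abs(own - 777.0).min() > 100.0


class TestFinalEnsemble:
    def _fitted(self, rng, specs=None):
        X, y, g = _panel(rng, n_mon=12, n_days=15)
        folds = make_folds(list(pd.unique(g)), n_folds=6, seed=0)
        specs = specs or [BaseLearnerSpec("ridge"), BaseLearnerSpec("lasso")]
        return fit_final(specs, X, y, g, folds), X, y, g, folds

    def test_weights_equal_meta_on_oof(self, rng):
        sl, X, y, g, folds = self._fitted(rng)
        oof = oof_predictions(sl.specs, X, y, g, folds)
        w = fit_meta_nnls(oof[list(sl.labels)], y, labels=list(sl.labels))
        np.testing.assert_allclose(sl.weights.weights, w.weights, atol=1e-12)

    def test_manifest_roundtrip_identical_predictions(self, rng, tmp_path):
        sl, X, *_ = self._fitted(rng)
        p = tmp_path / "model.pkl"
        sl.save(p)
        sl2 = sl.load(p)
        np.testing.assert_array_equal(sl.predict(X), sl2.predict(X))
        assert sl2.manifest == sl.manifest

    def test_combiner_linearity_and_weight_selection(self, rng):
        sl, X, *_ = self._fitted(rng)
        base = sl.base_predictions(X)
        w1 = replace(sl, weights=EnsembleWeights(sl.labels, np.array([1.0, 0.0]), 0.0))
        np.testing.assert_allclose(w1.predict(X, floor_at_zero=False), base[:, 0])
        doubled = replace(sl, weights=EnsembleWeights(
            sl.labels, 2 * sl.weights.weights, 0.0))
        np.testing.assert_allclose(doubled.predict(X, floor_at_zero=False),
                                   2 * sl.predict(X, floor_at_zero=False), rtol=1e-12)


class TestPredictGrid:
    def test_cell_day_count_and_schema(self, rng):
        sl, X, *_ = TestFinalEnsemble()._fitted(rng)
        grid = GridDomain(0.0, 0.0, 1000.0, 4, 3)
        dates = pd.date_range("2018-01-01", periods=2)
        n = grid.n_cells * len(dates)
        cells = np.tile(np.arange(grid.n_cells), len(dates))
        table = pd.DataFrame(rng.normal(size=(n, len(X.columns))), columns=X.columns)
        table["cell"] = cells
        table["date"] = np.repeat(dates, grid.n_cells)
        fld = predict_grid(sl, table, grid, dates)
        assert fld.values.shape == (2, 3, 4)
        assert np.isfinite(fld.values).sum() == n
        assert (fld.values >= 0).all()  # negatives floored

        with pytest.raises(ValueError, match="missing feature"):
            predict_grid(sl, table.drop(columns=["f0"]), grid, dates)


class TestVariableImportance:
    def test_single_year_single_feature(self, rng):
        X = pd.DataFrame({"f0": rng.normal(size=50)})
        y = 3 * X["f0"].to_numpy()
        m = BaseLearnerSpec("ridge").build().fit(X.to_numpy(), y)
        out = variable_importance({2018: {"ridge": m}}, ["f0"])
        assert out["proportion"].iloc[0] == pytest.approx(1.0)

    def test_proportions_sum_to_one(self, rng):
        X, y, g = _panel(rng, n_mon=10, n_days=10)
        models = {}
        for year in (2018, 2019):
            models[year] = {
                "LGBM": BaseLearnerSpec("LGBM", {"n_estimators": 30}, seed=year)
                .build().fit(X.to_numpy(), y),
                "ridge": BaseLearnerSpec("ridge").build().fit(X.to_numpy(), y),
            }
        out = variable_importance(models, list(X.columns))
        sums = out.groupby("learner")["proportion"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_planted_signal_ranks_first_for_trees(self, rng):
        X = pd.DataFrame(rng.normal(size=(400, 4)), columns=list("abcd"))
        y = 5.0 * X["c"].to_numpy() + rng.normal(scale=0.1, size=400)
        models = {2018: {
            "RF": BaseLearnerSpec("RF", {"n_estimators": 60}).build()
            .fit(X.to_numpy(), y),
            "LGBM": BaseLearnerSpec("LGBM", {"n_estimators": 60}).build()
            .fit(X.to_numpy(), y),
        }}
        out = variable_importance(models, list(X.columns))
        for learner in ("RF", "LGBM"):
            top = out[out["learner"] == learner].iloc[0]
            assert top["feature"] == "c"
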