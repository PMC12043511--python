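"""Training-table assembly, spatial folds, tuning, CV, and IJ uncertainty."""

import numpy as np
import pandas as pd
import pytest

from canopyscale import trait_models as tm
from canopyscale.covariates import CovariateStack
from canopyscale.grids import PixelGrid


# ---------------------------------------------------------------------------
# training table


def test_training_table_rows_and_lookup_oracle(small_landscape, small_cwm, small_stack):
    rasters, _, plot_layer = small_cwm
    table = tm.build_training_table(rasters, small_stack, plot_layer)
    r = rasters["leaf_n"]
    # independent recount: retained for >= 1 trait and all covariates finite
    any_retained = np.stack([x.retained for x in rasters.values()]).any(axis=0)
    cov_finite = np.isfinite(
        np.stack([small_stack[n] for n in small_stack.names()])
    ).all(axis=0)
    assert len(table) == int((any_retained & cov_finite).sum())
    # row values equal direct layer lookups at the stored coordinates
    sample = table.sample(20, random_state=0)
    for _, row in sample.iterrows():
        i, j = int(row["row"]), int(row["col"])
        assert row["B4"] == small_stack["B4"][i, j]
        if np.isfinite(row["cwm_leaf_n"]):
            assert row["cwm_leaf_n"] == r.values[i, j]
            assert r.retained[i, j]


def test_training_table_thinning_caps_per_plot(small_cwm, small_stack):
    rasters, _, plot_layer = small_cwm
    table = tm.build_training_table(rasters, small_stack, plot_layer,
                                    max_pixels_per_plot=10, seed=0)
    assert table.groupby("plot_id").size().max() <= 10


def test_dropping_covariate_layer_drops_one_column(small_landscape, small_cwm, small_stack):
    rasters, _, plot_layer = small_cwm
    full = tm.build_training_table(rasters, small_stack, plot_layer)
    reduced_stack = CovariateStack(small_stack.grid)
    for name in small_stack.names():
        if name != "ndre":
            reduced_stack.add(name, small_stack[name])
    reduced = tm.build_training_table(rasters, reduced_stack, plot_layer)
    assert len(full.columns) - len(reduced.columns) == 1


# ---------------------------------------------------------------------------
# folds


def _toy_table(sizes=(2, 3, 4)):
    rows = []
    rng = np.random.default_rng(0)
    for p, size in enumerate(sizes):
        for _ in range(size):
            rows.append({"plot_id": f"plot{p:03d}", "row": 0, "col": 0,
                         "cwm_t": rng.normal(), "x1": rng.normal()})
    return pd.DataFrame(rows)


def test_spatial_folds_sizes_and_count():
    table = _toy_table((2, 3, 4))
    folds = tm.spatial_block_folds(table)
    assert len(folds) == 3
    assert sorted(len(test) for _, _, test in folds) == [2, 3, 4]


def test_spatial_folds_no_leakage():
    table = _toy_table((5, 5, 5, 5))
    plot_col = table["plot_id"].to_numpy()
    for plot, train, test in tm.spatial_block_folds(table):
        assert set(plot_col[test]) == {plot}
        assert set(plot_col[train]) & set(plot_col[test]) == set()
        assert len(train) + len(test) == len(table)


def test_single_plot_rejected():
    with pytest.raises(ValueError, match="at least 2"):
        tm.spatial_block_folds(_toy_table((4,)))


# ---------------------------------------------------------------------------
# tuning


def _signal_table(n_plots=10, per_plot=30, noise=0.3, seed=0, p_noise=8):
    rng = np.random.default_rng(seed)
    n = n_plots * per_plot
    x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
    X_noise = rng.standard_normal((n, p_noise))
    y = x1 + 0.5 * x2 + noise * rng.standard_normal(n)
    data = {"plot_id": np.repeat([f"plot{p:03d}" for p in range(n_plots)], per_plot),
            "row": 0, "col": 0, "cwm_t": y, "x1": x1, "x2": x2}
    for k in range(p_noise):
        data[f"n{k}"] = X_noise[:, k]
    return pd.DataFrame(data)


def test_tune_single_candidate_returned_unchanged():
    table = _signal_table()
    spec = tm.tune_rf(table, "cwm_t", tree_grid=(300,), mtry_grid=(4,), seed=1)
    assert (spec.n_trees, spec.mtry) == (300, 4)


def test_tune_empty_grid_rejected():
    with pytest.raises(ValueError, match="empty"):
        tm.tune_rf(_signal_table(), "cwm_t", tree_grid=(), mtry_grid=(1,))


def test_tuned_mtry_matches_independent_grid_evaluation():
    """The tuned candidate's spatial-CV RMSE is close to the best achievable
    over the mtry grid (tuning tracks the true optimum, not OOB noise)."""
    for seed in (0, 1, 2):
        table = _signal_table(seed=seed)
        spec = tm.tune_rf(table, "cwm_t", tree_grid=(300,),
                          mtry_grid=(1, 3, 5, 7, 10), seed=seed)
        rmses = {
            mtry: tm.evaluate_cv(table, "cwm_t",
                                 tm.RFModelSpec(300, mtry, seed)).rmse
            for mtry in (1, 3, 5, 7, 10)
        }
        assert rmses[spec.mtry] <= min(rmses.values()) * 1.10


# ---------------------------------------------------------------------------
# cross-validation


def test_cv_perfect_predictor_ceiling():
    """Response duplicated into a covariate, no noise, deep trees -> R^2 >= 0.99."""
    table = _signal_table(noise=0.0, seed=2)
    table["leak"] = table["cwm_t"]
    spec = tm.RFModelSpec(n_trees=200, mtry=11, seed=0, min_samples_leaf=1)
    cv = tm.evaluate_cv(table, "cwm_t", spec)
    assert cv.r2 >= 0.99


def test_cv_metrics_match_independent_recomputation():
    table = _signal_table(seed=3)
    cv = tm.evaluate_cv(table, "cwm_t", tm.RFModelSpec(n_trees=100, mtry=3, seed=0))
    obs = cv.predictions["observed"].to_numpy()
    pred = cv.predictions["predicted"].to_numpy()
    sse = ((obs - pred) ** 2).sum()
    assert cv.r2 == pytest.approx(1 - sse / ((obs - obs.mean()) ** 2).sum(), abs=1e-12)
    assert cv.rmse == pytest.approx(np.sqrt(sse / len(obs)), abs=1e-12)
    # each pixel predicted exactly once
    assert len(cv.predictions) == len(table)
    assert np.isfinite(pred).all()


def test_cv_predictions_convex_in_training_range():
    table = _signal_table(seed=4)
    cv = tm.evaluate_cv(table, "cwm_t", tm.RFModelSpec(n_trees=100, mtry=3, seed=0))
    obs = cv.predictions["observed"]
    assert cv.predictions["predicted"].min() >= obs.min() - 1e-9
    assert cv.predictions["predicted"].max() <= obs.max() + 1e-9


# ---------------------------------------------------------------------------
# prediction + uncertainty


def _tiny_stack(n=8):
    grid = PixelGrid(0, 0, 10, n, n)
    stack = CovariateStack(grid)
    rng = np.random.default_rng(5)
    for name in ("x1", "x2", "n0", "n1", "n2", "n3", "n4", "n5", "n6", "n7"):
        stack.add(name, rng.standard_normal((n, n)))
    return stack


def test_se_nonnegative_and_tree_count_stable():
    """IJ s.e. is nonnegative everywhere and doubling the ensemble in the
    usage range (500 -> 1000 trees) does not increase the median s.e. beyond
    Monte-Carlo wiggle (3 replicates averaged)."""
    table = _signal_table(n_plots=6, per_plot=25)
    stack = _tiny_stack()
    medians = {}
    for n_trees in (500, 1000):
        meds = []
        for seed in range(3):
            tmap, _ = tm.fit_predict_uncertainty(
                table, "cwm_t", tm.RFModelSpec(n_trees=n_trees, mtry=3, seed=seed), stack
            )
            assert np.nanmin(tmap.se) >= 0.0
            meds.append(np.nanmedian(tmap.se))
        medians[n_trees] = np.mean(meds)
    assert medians[1000] <= medians[500] * 1.05


def test_noise_covariate_gets_lower_importance():
    table = _signal_table(noise=0.5, seed=6)
    stack = _tiny_stack()
    _, imp = tm.fit_predict_uncertainty(
        table, "cwm_t", tm.RFModelSpec(n_trees=300, mtry=3, seed=0), stack
    )
    imp = imp.set_index("covariate")
    assert imp.loc["x1", "importance_scaled"] == 1.0
    for k in range(8):
        assert imp.loc[f"n{k}", "importance_scaled"] < imp.loc["x1", "importance_scaled"]


def test_importance_scaling_idempotent():
    imp = pd.DataFrame({"covariate": ["a", "b"], "importance_raw": [2.0, 1.0],
                        "importance_scaled": [1.0, 0.5]})
    once = tm.scale_importance(imp)
    twice = tm.scale_importance(once)
    pd.testing.assert_frame_equal(once, twice)
    assert once["importance_scaled"].max() == 1.0


# ---------------------------------------------------------------------------
# forest mask


def test_forest_mask_boundary_inclusive():
    grid_shape = (1, 3)
    cover = np.array([[24.9, 25.0, 100.0]])
    maps = {"t": tm.TraitMap(prediction=np.ones(grid_shape), se=np.ones(grid_shape))}
    masked = tm.apply_forest_mask(maps, cover, threshold=25.0)
    assert np.isnan(masked["t"].prediction[0, 0])
    assert masked["t"].prediction[0, 1] == 1.0
    assert masked["t"].prediction[0, 2] == 1.0
    assert masked["t"].forest_mask_applied


def test_forest_mask_count_bookkeeping():
    rng = np.random.default_rng(7)
    cover = rng.uniform(0, 100, (10, 10))
    maps = {"t": tm.TraitMap(prediction=np.ones((10, 10)), se=np.ones((10, 10)))}
    masked = tm.apply_forest_mask(maps, cover, threshold=25.0)
    assert int(np.isnan(masked["t"].prediction).sum()) == int((cover < 25.0).sum())
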