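"""Random-forest trait models with spatial-block cross-validation.

Each trait's pixel CWM is regressed on the covariate stack with a random
forest. Model selection searches tree counts in {500, 1000, 1500} and mtry
(features per split) in 1-10; the selected model minimizes out-of-bag RMSE,
with candidates within a small relative tolerance of the minimum treated as
tied and resolved toward fewer trees, then smaller mtry (parsimony under
estimation noise, in the spirit of the one-standard-error rule).

Reported accuracy comes from plot-level spatial-block leave-one-out
cross-validation: every pixel of one plot is held out together, so the test
plot never shares data with its training set.

Prediction uncertainty is the infinitesimal-jackknife (IJ) standard error of
the bagged ensemble (Wager-Hastie-Efron estimator with the Monte-Carlo bias
correction, clipped at zero), computed from per-tree in-bag counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .covariates import CovariateStack
from .cwm_scaling import CWMRaster

DEFAULT_TREE_GRID = (500, 1000, 1500)
DEFAULT_MTRY_GRID = tuple(range(1, 11))
MIN_SAMPLES_LEAF = 5  # regression default of the ranger RF implementation


@dataclass(frozen=True)
class RFModelSpec:
    """Forest size and mtry; values default to the searched ranges."""

    n_trees: int = 500
    mtry: int = 3
    seed: int = 0
    min_samples_leaf: int = MIN_SAMPLES_LEAF

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.mtry < 1 or self.min_samples_leaf < 1:
            raise ValueError("n_trees, mtry and min_samples_leaf must be positive")


@dataclass
class CVResult:
    """Pooled out-of-fold predictions and accuracy of a spatial-block LOO CV."""

    predictions: pd.DataFrame  # columns: plot_id, observed, predicted
    r2: float
    rmse: float
    fold_plots: list[str]


@dataclass
class TraitMap:
    prediction: np.ndarray
    se: np.ndarray
    se_estimator: str = "infinitesimal-jackknife"
    forest_mask_applied: bool = False


# ---------------------------------------------------------------------------
# training table


def build_training_table(
    cwm: dict[str, CWMRaster],
    stack: CovariateStack,
    plot_layer: np.ndarray,
    max_pixels_per_plot: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One row per pixel retained for at least one trait.

    Columns: ``plot_id``, ``row``, ``col``, one response column
    ``cwm_<trait>`` per trait (NaN where that trait is not retained), and the
    covariates sampled at pixel centres. Rows with any missing covariate are
    dropped. ``max_pixels_per_plot`` takes a seeded subsample per plot --
    adjacent 10-m pixels within a plot are strongly spatially autocorrelated,
    so thinning trades little information for a large cost saving.
    """
    grid = stack.grid
    any_retained = np.zeros(grid.shape, dtype=bool)
    for r in cwm.values():
        if r.grid != grid:
            raise ValueError("CWM raster grid differs from covariate grid")
        any_retained |= r.retained
    rows, cols = np.nonzero(any_retained)
    if len(rows) == 0:
        raise ValueError("no retained CWM pixels")

    data = {
        "plot_id": [f"plot{plot_layer[i, j]:03d}" for i, j in zip(rows, cols)],
        "row": rows,
        "col": cols,
    }
    for t, r in cwm.items():
        vals = r.values[rows, cols].copy()
        vals[~r.retained[rows, cols]] = np.nan
        data[f"cwm_{t}"] = vals
    for name in stack.names():
        data[name] = stack[name][rows, cols]
    table = pd.DataFrame(data)
    cov_ok = table[stack.names()].notna().all(axis=1)
    table = table[cov_ok].reset_index(drop=True)
    if max_pixels_per_plot is not None:
        rng = np.random.default_rng(seed)
        keep = []
        for _, idx in table.groupby("plot_id").indices.items():
            if len(idx) > max_pixels_per_plot:
                idx = rng.choice(idx, size=max_pixels_per_plot, replace=False)
            keep.append(np.sort(idx))
        table = table.iloc[np.concatenate(keep)].reset_index(drop=True)
    return table


def covariate_names(table: pd.DataFrame) -> list[str]:
    return [
        c for c in table.columns
        if c not in ("plot_id", "row", "col") and not c.startswith("cwm_")
    ]


def spatial_block_folds(table: pd.DataFrame) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Plot-level leave-one-out folds: (held-out plot id, train idx, test idx).

    All pixels of a plot share a fold; a test fold never shares a plot with
    its training rows.
    """
    plots = table["plot_id"].unique()
    if len(plots) < 2:
        raise ValueError("spatial-block CV needs at least 2 plots")
    folds = []
    plot_col = table["plot_id"].to_numpy()
    for p in plots:
        test = np.nonzero(plot_col == p)[0]
        train = np.nonzero(plot_col != p)[0]
        folds.append((str(p), train, test))
    return folds


# ---------------------------------------------------------------------------
# in-bag bookkeeping (scikit-learn draws bootstrap indices from each tree's
# random_state; regenerating them gives the exact in-bag counts)


def _inbag_counts(forest: RandomForestRegressor, n_samples: int) -> np.ndarray:
    return _inbag_counts_for(forest.estimators_, n_samples, forest.max_samples)


def _inbag_counts_for(trees, n_samples: int, max_samples=None) -> np.ndarray:
    from sklearn.ensemble._forest import (
        _generate_sample_indices,
        _get_n_samples_bootstrap,
    )

    n_boot = _get_n_samples_bootstrap(n_samples, max_samples, None)
    counts = np.zeros((len(trees), n_samples), dtype=np.float64)
    for b, tree in enumerate(trees):
        idx = _generate_sample_indices(tree.random_state, n_samples, n_boot, None)
        counts[b] = np.bincount(idx, minlength=n_samples)
    return counts


def _fit_forest(X: np.ndarray, y: np.ndarray, spec: RFModelSpec,
                warm: RandomForestRegressor | None = None) -> RandomForestRegressor:
    if warm is None:
        forest = RandomForestRegressor(
            n_estimators=spec.n_trees,
            max_features=spec.mtry,
            min_samples_leaf=spec.min_samples_leaf,
            bootstrap=True,
            random_state=spec.seed,
            n_jobs=1,
        )
    else:
        forest = warm
        forest.set_params(n_estimators=spec.n_trees)
    forest.fit(X, y)
    return forest


def _oob_rmse(forest: RandomForestRegressor, X: np.ndarray, y: np.ndarray) -> float:
    """Out-of-bag RMSE from per-tree predictions on the training rows."""
    n = len(y)
    inbag = _inbag_counts(forest, n)
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    for b, tree in enumerate(forest.estimators_):
        oob = inbag[b] == 0
        if oob.any():
            pred_sum[oob] += tree.predict(X[oob])
            pred_cnt[oob] += 1
    seen = pred_cnt > 0
    resid = y[seen] - pred_sum[seen] / pred_cnt[seen]
    return float(np.sqrt(np.mean(resid**2)))


def _tree_predictions(trees, X: np.ndarray) -> np.ndarray:
    """(n_trees, n_rows) per-tree predictions via leaf-value lookup."""
    out = np.empty((len(trees), len(X)))
    for b, tree in enumerate(trees):
        leaves = tree.tree_.apply(np.asarray(X, dtype=np.float32))
        out[b] = tree.tree_.value[leaves, 0, 0]
    return out


# ---------------------------------------------------------------------------
# tuning


def tune_rf(
    table: pd.DataFrame,
    response: str,
    tree_grid: tuple[int, ...] = DEFAULT_TREE_GRID,
    mtry_grid: tuple[int, ...] = DEFAULT_MTRY_GRID,
    seed: int = 0,
    rmse_rel_tol: float = 0.02,
    max_rows: int | None = None,
) -> RFModelSpec:
    """Select (n_trees, mtry) by out-of-bag RMSE over the searched ranges.

    A two-stage search keeps the grid affordable at desk scale: the mtry
    range is swept at the smallest tree count (OOB RMSE stabilizes well
    before 500 trees, so the mtry ranking is reliable there), then the
    tree-count ladder is grown for the winning mtry via warm starts (a
    500-tree forest is a prefix of the 1500-tree one). Candidates whose RMSE
    is within ``rmse_rel_tol`` (relative) of the best are tied; ties resolve
    to smaller mtry, then fewer trees -- parsimony under OOB estimation
    noise, in the spirit of the one-standard-error rule. ``max_rows`` tunes
    on a seeded row subsample.
    """
    if not tree_grid or not mtry_grid:
        raise ValueError("candidate grid is empty")
    sub = table.dropna(subset=[response])
    if max_rows is not None and len(sub) > max_rows:
        rng = np.random.default_rng(seed)
        sub = sub.iloc[np.sort(rng.choice(len(sub), size=max_rows, replace=False))]
    X = sub[covariate_names(table)].to_numpy()
    y = sub[response].to_numpy()
    p = X.shape[1]
    n = len(y)
    Xf = np.asarray(X, dtype=np.float32)
    ladder = sorted(tree_grid)
    base_trees = ladder[0]

    def oob_terms(trees):
        inbag = _inbag_counts_for(trees, n)
        preds = _tree_predictions(trees, Xf)
        oob = inbag == 0
        return (preds * oob).sum(axis=0), oob.sum(axis=0)

    def rmse_from(pred_sum, pred_cnt):
        seen = pred_cnt > 0
        resid = y[seen] - pred_sum[seen] / pred_cnt[seen]
        return float(np.sqrt(np.mean(resid**2)))

    # stage 1: mtry sweep at the base tree count
    mtry_rmse: dict[int, float] = {}
    for mtry in mtry_grid:
        if mtry > p:
            continue
        forest = RandomForestRegressor(
            n_estimators=base_trees, max_features=mtry,
            min_samples_leaf=MIN_SAMPLES_LEAF, bootstrap=True,
            random_state=seed, n_jobs=1,
        )
        forest.fit(X, y)
        mtry_rmse[mtry] = rmse_from(*oob_terms(forest.estimators_))
    if not mtry_rmse:
        raise ValueError("no feasible candidates (mtry larger than feature count)")
    best = min(mtry_rmse.values())
    best_mtry = min(m for m, v in mtry_rmse.items() if v <= best * (1.0 + rmse_rel_tol))

    # stage 2: tree-count ladder for the winning mtry
    warm = RandomForestRegressor(
        n_estimators=0, max_features=best_mtry, min_samples_leaf=MIN_SAMPLES_LEAF,
        bootstrap=True, random_state=seed, warm_start=True, n_jobs=1,
    )
    pred_sum = np.zeros(n)
    pred_cnt = np.zeros(n)
    done = 0
    tree_rmse: dict[int, float] = {}
    for n_trees in ladder:
        warm.set_params(n_estimators=n_trees)
        warm.fit(X, y)
        s, c = oob_terms(warm.estimators_[done:])
        pred_sum += s
        pred_cnt += c
        done = n_trees
        tree_rmse[n_trees] = rmse_from(pred_sum, pred_cnt)
    best = min(tree_rmse.values())
    best_trees = min(t for t, v in tree_rmse.items() if v <= best * (1.0 + rmse_rel_tol))
    return RFModelSpec(n_trees=best_trees, mtry=best_mtry, seed=seed)


# ---------------------------------------------------------------------------
# evaluation


def evaluate_cv(table: pd.DataFrame, response: str, spec: RFModelSpec) -> CVResult:
    """Plot-level spatial-block LOO CV; pooled out-of-fold R^2 and RMSE."""
    folds = spatial_block_folds(table.dropna(subset=[response]).reset_index(drop=True))
    sub = table.dropna(subset=[response]).reset_index(drop=True)
    X = sub[covariate_names(table)].to_numpy()
    y = sub[response].to_numpy()
    pred = np.full(len(y), np.nan)
    fold_plots = []
    for plot, train, test in folds:
        if len(train) == 0:
            raise ValueError(f"fold {plot} has no training rows")
        forest = _fit_forest(X[train], y[train], spec)
        pred[test] = forest.predict(X[test])
        fold_plots.append(plot)
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst
    rmse = math.sqrt(sse / len(y))
    frame = pd.DataFrame({"plot_id": sub["plot_id"], "observed": y, "predicted": pred})
    return CVResult(predictions=frame, r2=r2, rmse=rmse, fold_plots=fold_plots)


# ---------------------------------------------------------------------------
# fit + predict with uncertainty


def fit_predict_uncertainty(
    table: pd.DataFrame,
    response: str,
    spec: RFModelSpec,
    stack: CovariateStack,
    tree_chunk: int = 100,
) -> tuple[TraitMap, pd.DataFrame]:
    """Fit on all rows, predict every stack pixel, and attach IJ uncertainty.

    The infinitesimal-jackknife variance at a pixel x is
    ``sum_i Cov_b(N_bi, t_b(x))^2`` over training rows i (N_bi the in-bag
    count of row i in tree b, t_b the tree prediction), with the
    Wager-Hastie-Efron Monte-Carlo bias correction, clipped at zero. Returns
    the trait map and the impurity-importance table (raw and scaled to a max
    of 1).
    """
    sub = table.dropna(subset=[response])
    names = covariate_names(table)
    X = sub[names].to_numpy()
    y = sub[response].to_numpy()
    forest = _fit_forest(X, y, spec)

    grid = stack.grid
    Xp = stack.as_matrix(names)
    valid = np.isfinite(Xp).all(axis=1)
    n, B = len(y), len(forest.estimators_)

    inbag = _inbag_counts(forest, n)
    Nc = inbag - inbag.mean(axis=0, keepdims=True)  # (B, n)

    pred_sum = np.zeros(valid.sum())
    cov_sum = np.zeros((n, valid.sum()))  # sum_b Nc[b,i] * t_b(x)
    sq_sum = np.zeros(valid.sum())
    Xv = Xp[valid]
    for start in range(0, B, tree_chunk):
        chunk = forest.estimators_[start:start + tree_chunk]
        T = np.stack([t.predict(Xv) for t in chunk], axis=0)  # (b, n_pix)
        pred_sum += T.sum(axis=0)
        sq_sum += (T**2).sum(axis=0)
        cov_sum += Nc[start:start + tree_chunk].T @ T
    mean = pred_sum / B
    var_ij = ((cov_sum / B) ** 2).sum(axis=0)
    # Monte-Carlo bias correction (Wager, Hastie & Efron 2014)
    tree_var = sq_sum / B - mean**2
    var_ij = np.maximum(var_ij - n * tree_var / B, 0.0)

    pred_layer = np.full(grid.shape, np.nan).ravel()
    se_layer = np.full(grid.shape, np.nan).ravel()
    pred_layer[valid] = mean
    se_layer[valid] = np.sqrt(var_ij)

    importance = pd.DataFrame(
        {
            "covariate": names,
            "importance_raw": forest.feature_importances_,
        }
    )
    m = importance["importance_raw"].max()
    importance["importance_scaled"] = importance["importance_raw"] / (m if m > 0 else 1.0)

    trait_map = TraitMap(
        prediction=pred_layer.reshape(grid.shape),
        se=se_layer.reshape(grid.shape),
    )
    return trait_map, importance


def scale_importance(importance: pd.DataFrame) -> pd.DataFrame:
    """Rescale the raw impurity importances to a [0, 1] scale (max = 1)."""
    out = importance.copy()
    m = out["importance_raw"].max()
    out["importance_scaled"] = out["importance_raw"] / (m if m > 0 else 1.0)
    return out


def apply_forest_mask(
    maps: dict[str, TraitMap], forest_cover: np.ndarray, threshold: float = 25.0
) -> dict[str, TraitMap]:
    """Mask pixels below the forest-cover threshold (percent, inclusive keep).

    A pixel with cover exactly at the threshold is kept ("a minimum of 25%
    forest cover").
    """
    cover = np.asarray(forest_cover, dtype=float)
    below = cover < threshold
    out = {}
    for t, m in maps.items():
        if m.prediction.shape != cover.shape:
            raise ValueError("forest-cover layer is not co-registered with the maps")
        pred = m.prediction.copy()
        se = m.se.copy()
        pred[below] = np.nan
        se[below] = np.nan
        out[t] = TraitMap(prediction=pred, se=se, se_estimator=m.se_estimator,
                          forest_mask_applied=True)
    return out
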