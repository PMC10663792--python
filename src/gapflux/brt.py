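"""Boosted regression trees predicting fluxes from layered biomass.

Stage-wise gradient boosting of shallow regression trees with shrinkage
(learning rate), stochastic subsampling (bag fraction) and an absolute-error
(Laplace) loss, as in the gbm/dismo family of BRT tools; LightGBM provides
the boosting engine (``objective="l1"``, per-stage bagging, leaf count =
interaction depth + 1, early stopping on out-of-sample loss). For every
combination of target (GPP, NPP, tau), horizontal resolution (cell edge),
vertical resolution (layer width dh) and forest category (all / disturbed /
mature), the hyperparameter grid is searched, the number of boosting stages
is chosen by out-of-sample loss on a portion of the training data, and the
selected model is scored on a held-out validation half.

Training sets are a uniformly random half of the stand-year records, capped
at 15 900 rows; the remainder is the validation set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import lightgbm as lgb
import numpy as np
import pandas as pd

# noise from the LightGBM/sklearn interface when numpy arrays round-trip
warnings.filterwarnings("ignore",
                        message="X does not have valid feature names")

from .profile import ProfileSpec, layer_columns

__all__ = [
    "BRTConfig",
    "FitResult",
    "default_grid",
    "split_train_validation",
    "fit_brt",
    "evaluate",
    "grid_search",
    "resolution_sweep",
    "TRAIN_FRACTION",
    "TRAIN_CAP",
]

log = logging.getLogger(__name__)

TRAIN_FRACTION = 0.5
TRAIN_CAP = 15_900

LEARNING_RATES = (0.05, 0.01, 0.005)
BAG_FRACTIONS = (0.3, 0.5, 0.66)


@dataclass(frozen=True)
class BRTConfig:
    """One hyperparameter grid point.

    ``tree_complexity`` is the interaction depth of each tree; ``loss`` is
    the error structure minimized during boosting ("laplace" = absolute
    error, "gaussian" = squared error). ``cv_folds`` only applies when stage
    selection uses k-fold cross-validation instead of the default single
    held-out fold.
    """

    learning_rate: float = 0.01
    bag_fraction: float = 0.5
    tree_complexity: int = 3
    loss: str = "laplace"
    cv_folds: int = 10
    n_stages_max: int = 2000
    rng_seed: int = 0

    @property
    def lgb_objective(self) -> str:
        return {"laplace": "l1", "gaussian": "l2"}[self.loss]


def tree_complexities(dh: float) -> tuple[int, ...]:
    """Interaction depths tested per vertical resolution: 3 for coarse
    layers (dh = 20, 100 m), 5 for dh = 10 m, and both 5 and 7 for dh = 2 m."""
    if dh in (20.0, 100.0, 20, 100):
        return (3,)
    if dh in (10.0, 10):
        return (5,)
    if dh in (2.0, 2):
        return (5, 7)
    raise ValueError(f"unsupported layer width dh = {dh}")


def default_grid(dh: float,
                 learning_rates: tuple[float, ...] = LEARNING_RATES,
                 bag_fractions: tuple[float, ...] = BAG_FRACTIONS,
                 complexities: tuple[int, ...] | None = None,
                 **kwargs) -> list[BRTConfig]:
    """Full hyperparameter grid for a vertical resolution (9 or 18 points)."""
    return [BRTConfig(learning_rate=lr, bag_fraction=bf, tree_complexity=tc,
                      **kwargs)
            for tc in (complexities or tree_complexities(dh))
            for lr in learning_rates
            for bf in bag_fractions]


def split_train_validation(table: pd.DataFrame, fraction: float = TRAIN_FRACTION,
                           cap: int = TRAIN_CAP,
                           seed: int | np.random.Generator = 0,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniformly random train/validation split without replacement.

    Training size is ``min(floor(fraction * n), cap)``; every remaining row
    goes to validation.
    """
    n = len(table)
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_train = min(int(np.floor(fraction * n)), cap)
    perm = rng.permutation(n)
    return (table.iloc[perm[:n_train]].reset_index(drop=True),
            table.iloc[perm[n_train:]].reset_index(drop=True))


@dataclass
class FittedBRT:
    """A boosting ensemble with its selected stage count and search loss."""

    model: "lgb.LGBMRegressor | None"
    config: BRTConfig
    n_stages: int
    holdout_loss: float
    constant: float | None = None  # degenerate constant-target fallback

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.constant is not None:
            return np.full(X.shape[0], self.constant)
        return self.model.predict(X)


def _stage_selection_split(n: int, rng: np.random.Generator,
                           holdout: float = 0.2):
    perm = rng.permutation(n)
    n_val = max(1, int(round(holdout * n)))
    return perm[n_val:], perm[:n_val]


def _make_booster(config: BRTConfig, rng: np.random.Generator,
                  n_estimators: int) -> "lgb.LGBMRegressor":
    # tree_complexity counts splits (gbm's interaction depth), so each tree
    # carries tc+1 leaves grown best-first; min_child_samples matches gbm's
    # n.minobsinnode default of 10
    return lgb.LGBMRegressor(
        objective=config.lgb_objective,
        learning_rate=config.learning_rate,
        subsample=config.bag_fraction,
        subsample_freq=1,
        num_leaves=config.tree_complexity + 1,
        min_child_samples=10,
        n_estimators=n_estimators,
        n_jobs=1,
        force_col_wise=True,
        random_state=int(rng.integers(2**31 - 1)),
        verbose=-1,
    )


def fit_brt(X, y, config: BRTConfig,
            stage_selection: str = "holdout") -> FittedBRT:
    """Fit one boosted ensemble and choose its number of stages.

    The training portion is split once more: most rows fit the stage-wise
    ensemble, the rest provide out-of-sample loss estimates from which the
    best stage count is taken (early stopping once the loss curve has not
    improved for 100 stages). The selected stage count is then refit on the
    whole training portion. ``stage_selection="cv"`` replaces the single
    held-out fold with ``config.cv_folds``-fold cross-validation of the
    loss curve.

    A constant target yields a constant predictor (with a warning).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.ptp(y) == 0:
        log.warning("constant target: returning constant predictor")
        return FittedBRT(None, config, 0, 0.0, constant=float(y[0]))
    rng = np.random.default_rng(config.rng_seed)

    if stage_selection == "cv":
        curve = _cv_loss_curve(X, y, config, rng)
        n_best = int(np.argmin(curve)) + 1
        best_loss = float(curve.min())
    else:
        fit_ix, val_ix = _stage_selection_split(len(y), rng)
        n_best, best_loss = _early_stopped_stages(
            X[fit_ix], y[fit_ix], X[val_ix], y[val_ix], config, rng)

    model = _make_booster(config, rng, n_estimators=n_best)
    model.fit(X, y)
    return FittedBRT(model, config, n_best, best_loss)


def _early_stopped_stages(Xf, yf, Xv, yv, config: BRTConfig,
                          rng: np.random.Generator,
                          patience: int = 100) -> tuple[int, float]:
    """Best stage count and loss from one held-out fold."""
    model = _make_booster(config, rng, n_estimators=config.n_stages_max)
    model.fit(Xf, yf, eval_set=[(Xv, yv)], eval_metric=config.lgb_objective,
              callbacks=[lgb.early_stopping(patience, verbose=False)])
    n_best = int(model.best_iteration_ or config.n_stages_max)
    best_loss = float(model.best_score_["valid_0"][config.lgb_objective])
    return n_best, best_loss


def _cv_loss_curve(X, y, config: BRTConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Mean held-out loss per boosting stage over k folds."""
    k = config.cv_folds
    folds = rng.permutation(len(y)) % k
    n_stages = min(config.n_stages_max, 500)
    curves = np.zeros((k, n_stages))
    for f in range(k):
        tr = folds != f
        hist: dict = {}
        model = _make_booster(config, rng, n_estimators=n_stages)
        model.fit(X[tr], y[tr], eval_set=[(X[~tr], y[~tr])],
                  eval_metric=config.lgb_objective,
                  callbacks=[lgb.record_evaluation(hist)])
        curves[f] = hist["valid_0"][config.lgb_objective]
    return curves.mean(axis=0)


def evaluate(model: FittedBRT, X, y) -> dict[str, float]:
    """Validation scores: squared-Pearson r2, 1 - SSres/SStot, and RMSE.

    Constant predictions give r2 = 0 by convention.
    """
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty validation set")
    pred = model.predict(X)
    rmse = float(np.sqrt(np.mean((pred - y)**2)))
    if np.ptp(pred) == 0 or np.ptp(y) == 0:
        r2 = 0.0
    else:
        r = np.corrcoef(pred, y)[0, 1]
        r2 = float(r * r)
    sstot = float(np.sum((y - y.mean())**2))
    r2_ss = float(1.0 - np.sum((y - pred)**2) / sstot) if sstot > 0 else 0.0
    return {"r2": r2, "r2_ss": r2_ss, "rmse": rmse}


def grid_search(X_train, y_train, grid: list[BRTConfig],
                stage_selection: str = "holdout") -> FittedBRT:
    """Fit every grid point and keep the lowest out-of-sample loss.

    Ties resolve toward the smaller learning rate (the more conservative
    ensemble).
    """
    fits = [fit_brt(X_train, y_train, cfg, stage_selection) for cfg in grid]
    fits.sort(key=lambda f: (f.holdout_loss, f.config.learning_rate))
    return fits[0]


@dataclass
class FitResult:
    """Validation outcome of one (target, resolution, category) combination."""

    target: str
    dh: float
    cell_edge: float
    category: str
    config: BRTConfig
    n_stages: int
    r2_validation: float
    r2_ss_validation: float
    rmse_validation: float
    n_train: int
    n_validation: int


def _features(table: pd.DataFrame, spec: ProfileSpec) -> np.ndarray:
    return table[layer_columns(spec)].to_numpy(float)


def resolution_sweep(tables: dict[tuple[float, float], pd.DataFrame],
                     targets: tuple[str, ...] = ("gpp", "npp", "tau"),
                     categories: tuple[str, ...] = ("all", "disturbed", "mature"),
                     seed: int = 0,
                     learning_rates: tuple[float, ...] = LEARNING_RATES,
                     bag_fractions: tuple[float, ...] = BAG_FRACTIONS,
                     stage_selection: str = "holdout",
                     min_records: int = 50,
                     complexities: tuple[int, ...] | None = None,
                     n_stages_max: int = 2000) -> pd.DataFrame:
    """Grid-searched BRT fits for every combination in the study design.

    ``tables`` maps ``(cell_edge, dh)`` to the stand-year table at that
    resolution. Category models are trained and validated strictly within
    their category. Combinations with too few records or a degenerate
    target are skipped with a logged reason. Returns one row per fit
    (the data behind the resolution-comparison figures).
    """
    root = np.random.SeedSequence(seed)
    rows = []
    combos = [(t, ce, dh, cat) for t in targets
              for (ce, dh) in sorted(tables) for cat in categories]
    for i, (target, cell_edge, dh, category) in enumerate(combos):
        spec = ProfileSpec(dh=dh, cell_edge=cell_edge)
        table = tables[(cell_edge, dh)]
        if category != "all":
            table = table[table["category"] == category]
        if target == "tau":
            table = table[table["tau"].notna()]
        if len(table) < min_records:
            log.warning("skip %s %s ha dh=%s %s: only %d records",
                        target, spec.cell_area_ha, dh, category, len(table))
            continue
        sub_seed = np.random.SeedSequence(entropy=root.entropy, spawn_key=(i,))
        split_rng = np.random.default_rng(sub_seed)
        train, val = split_train_validation(table, seed=split_rng)
        if train[target].nunique() < 2:
            log.warning("skip %s %s ha dh=%s %s: degenerate target",
                        target, spec.cell_area_ha, dh, category)
            continue
        grid = default_grid(dh, learning_rates, bag_fractions,
                            complexities=complexities,
                            rng_seed=int(split_rng.integers(2**31 - 1)),
                            n_stages_max=n_stages_max)
        best = grid_search(_features(train, spec), train[target].to_numpy(),
                           grid, stage_selection)
        scores = evaluate(best, _features(val, spec), val[target].to_numpy())
        rows.append({
            "target": target, "dh": dh, "cell_edge": cell_edge,
            "cell_area_ha": spec.cell_area_ha, "category": category,
            "learning_rate": best.config.learning_rate,
            "bag_fraction": best.config.bag_fraction,
            "tree_complexity": best.config.tree_complexity,
            "n_stages": best.n_stages,
            "r2_validation": scores["r2"],
            "r2_ss_validation": scores["r2_ss"],
            "rmse_validation": scores["rmse"],
            "n_train": len(train), "n_validation": len(val),
        })
    columns = ["target", "dh", "cell_edge", "cell_area_ha", "category",
               "learning_rate", "bag_fraction", "tree_complexity", "n_stages",
               "r2_validation", "r2_ss_validation", "rmse_validation",
               "n_train", "n_validation"]
    return pd.DataFrame(rows, columns=columns)
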