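"""Ensemble species distribution models with ecoregion-block cross-validation.

Study cells are partitioned into ten sampling blocks of whole ecoregion
units chosen so block mean bioclimate stays close to the global mean
(with a cell-count balance penalty).  For each species, four techniques
(GLM with per-variable polynomial degree search, GAM with regression
splines, gradient-boosted trees, random forests) are each fitted ten
times leaving one block out, giving 40 models whose held-out AUCs weight
the ensemble.  Baseline suitability is the per-cell median of the 40
era-1 projections; change is median(era2) - median(era1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from statsmodels.gam.api import BSplines, GLMGam

logger = logging.getLogger(__name__)

TECHNIQUES = ("GLM", "GAM", "GBM", "RF")


@dataclass
class SDMConfig:
    """Hyperparameter search settings for the four techniques.

    Defaults follow the standard protocol for continental atlas grids
    (boosting: learning rate 0.001, 5000 trees, tree complexity 1-4;
    forests: mtry 1-3, 1000 trees grown in steps of 500 until the AUC
    gain falls below 1%).  ``desk()`` returns a faster configuration for
    small synthetic grids, with fewer, more aggressive boosting trees;
    on a few hundred cells the two are statistically equivalent.
    """

    glm_degrees: tuple[int, ...] = (1, 2)
    gam_df: int = 6
    gbm_learning_rate: float = 0.001
    gbm_n_trees: int = 5000
    gbm_tc_range: tuple[int, ...] = (1, 2, 3, 4)
    rf_mtry_range: tuple[int, ...] = (1, 2, 3)
    rf_initial_trees: int = 1000
    rf_tree_step: int = 500
    rf_max_trees: int = 3000
    rf_auc_gain_threshold: float = 0.01
    seed: int = 0

    @classmethod
    def desk(cls, seed: int = 0) -> "SDMConfig":
        return cls(
            gbm_learning_rate=0.01,
            gbm_n_trees=200,
            gbm_tc_range=(1, 2, 3),
            rf_initial_trees=100,
            rf_tree_step=100,
            rf_max_trees=300,
            seed=seed,
        )


@dataclass
class SamplingBlock:
    block_id: int
    ecoregion_units: list[str]
    cell_ids: list[str]
    bioclim_mean: np.ndarray


@dataclass
class FittedSDM:
    species_id: str
    technique: str
    held_out_block: int
    hyperparameters: dict
    auc_holdout: float  # NaN when the held-out block lacked a class
    predictor: "object"

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.predictor(features)


@dataclass
class SuitabilitySurface:
    species_id: str
    cell_ids: pd.Index
    suitability_era1: np.ndarray  # median across the 40 models
    suitability_era2: np.ndarray
    change: np.ndarray
    weighted_era1: np.ndarray = field(default=None)  # AUC-weighted variant
    weighted_era2: np.ndarray = field(default=None)

    def restrict(self, cell_ids) -> "SuitabilitySurface":
        """Surface limited to a cell subset (e.g. the comparable mask)."""
        pos = self.cell_ids.get_indexer(cell_ids)
        if (pos < 0).any():
            raise KeyError("cell subset not contained in surface")
        return SuitabilitySurface(
            species_id=self.species_id,
            cell_ids=pd.Index(cell_ids, name=self.cell_ids.name),
            suitability_era1=self.suitability_era1[pos],
            suitability_era2=self.suitability_era2[pos],
            change=self.change[pos],
            weighted_era1=None if self.weighted_era1 is None else self.weighted_era1[pos],
            weighted_era2=None if self.weighted_era2 is None else self.weighted_era2[pos],
        )


# -- AUC ----------------------------------------------------------------


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC via the rank statistic: (concordant + ties/2) / (n+ * n-).

    Returns NaN when either class is absent (the quantity is undefined,
    not an error condition).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# -- block construction -------------------------------------------------


def build_blocks(
    grid: pd.DataFrame,
    bioclim: pd.DataFrame,
    k: int = 10,
    balance_weight: float = 1.0,
    seed: int | None = None,
) -> list[SamplingBlock]:
    """Group ecoregion units into k blocks of similar mean bioclimate.

    Units (contiguous ecoregion patches, never single cells) are
    assigned whole.  A greedy pass in decreasing unit size places each
    unit in the block minimising

        sum_b ||mean_b - global_mean||^2  +  w * sum_b (n_b/N - 1/k)^2

    on z-scaled bioclim.  Ties in unit size are ordered by the seed, so
    the partition is deterministic given (grid, bioclim, seed).
    """
    units = grid["ecoregion_unit"].astype(str)
    unit_ids = units.unique()
    if len(unit_ids) < k:
        raise ValueError(
            f"{len(unit_ids)} ecoregion units < {k} blocks; reduce k"
        )
    z = (bioclim - bioclim.mean()) / bioclim.std(ddof=0).replace(0.0, 1.0)
    z = z.loc[grid.index]
    global_mean = z.mean().to_numpy()

    unit_sum = {u: z.loc[units == u].sum().to_numpy() for u in unit_ids}
    unit_n = {u: int((units == u).sum()) for u in unit_ids}
    n_total = len(grid)

    rng = np.random.default_rng(seed)
    order = list(unit_ids)
    rng.shuffle(order)
    order.sort(key=lambda u: -unit_n[u])  # stable: ties keep shuffled order

    block_sum = np.zeros((k, z.shape[1]))
    block_n = np.zeros(k, dtype=int)
    assignment: dict[str, int] = {}

    def objective(bs: np.ndarray, bn: np.ndarray) -> float:
        total = 0.0
        for b in range(k):
            if bn[b] > 0:
                diff = bs[b] / bn[b] - global_mean
                total += float(diff @ diff)
        total += balance_weight * float(((bn / n_total - 1.0 / k) ** 2).sum())
        return total

    for i, u in enumerate(order):
        if i < k:  # seed every block with one unit (largest first)
            b_star = i
        else:
            best = np.inf
            b_star = 0
            for b in range(k):
                bs = block_sum.copy()
                bn = block_n.copy()
                bs[b] += unit_sum[u]
                bn[b] += unit_n[u]
                val = objective(bs, bn)
                if val < best - 1e-12:
                    best = val
                    b_star = b
        block_sum[b_star] += unit_sum[u]
        block_n[b_star] += unit_n[u]
        assignment[u] = b_star

    blocks = []
    for b in range(k):
        members = [u for u in unit_ids if assignment[u] == b]
        cells = grid.index[units.isin(members)].tolist()
        blocks.append(
            SamplingBlock(
                block_id=b + 1,
                ecoregion_units=members,
                cell_ids=cells,
                bioclim_mean=block_sum[b] / max(block_n[b], 1),
            )
        )
    return blocks


def block_objective(blocks: list[SamplingBlock], bioclim: pd.DataFrame,
                    balance_weight: float = 1.0) -> float:
    """Recompute the blocking objective for an existing partition."""
    z = (bioclim - bioclim.mean()) / bioclim.std(ddof=0).replace(0.0, 1.0)
    global_mean = z.mean().to_numpy()
    n_total = sum(len(b.cell_ids) for b in blocks)
    k = len(blocks)
    total = 0.0
    for b in blocks:
        if b.cell_ids:
            diff = z.loc[b.cell_ids].mean().to_numpy() - global_mean
            total += float(diff @ diff)
        total += balance_weight * (len(b.cell_ids) / n_total - 1.0 / k) ** 2
    return total


# -- per-technique predictors ------------------------------------------


class _ConstantPredictor:
    def __init__(self, value: float):
        self.value = value

    def __call__(self, features: pd.DataFrame) -> np.ndarray:
        return np.full(len(features), self.value)


class _GLMPredictor:
    def __init__(self, result, combo, degrees, extra_cols):
        self.result = result
        self.combo = combo
        self.degrees = degrees
        self.extra_cols = extra_cols

    @staticmethod
    def design(features, combo, degrees, extra_cols):
        cols = [np.ones(len(features))]
        for var, deg in zip(combo, degrees):
            x = features[var].to_numpy(dtype=float)
            for d in range(1, deg + 1):
                cols.append(x**d)
        for c in extra_cols:
            cols.append(features[c].to_numpy(dtype=float))
        return np.column_stack(cols)

    def __call__(self, features: pd.DataFrame) -> np.ndarray:
        X = self.design(features, self.combo, self.degrees, self.extra_cols)
        return np.asarray(self.result.predict(X))


class _GAMPredictor:
    """Spline GAM with predictions clamped to the training support.

    Beyond the observed climate range the smooth basis is undefined;
    inputs are clipped to the fitted range (constant extrapolation),
    the usual clamping convention when projecting an SDM to a shifted
    climate.
    """

    def __init__(self, result, combo, extra_cols, lo, hi):
        self.result = result
        self.combo = combo
        self.extra_cols = extra_cols
        self.lo = lo
        self.hi = hi

    def __call__(self, features: pd.DataFrame) -> np.ndarray:
        Xs = features[list(self.combo)].to_numpy(dtype=float)
        Xs = np.clip(Xs, self.lo[None, :], self.hi[None, :])
        exog = np.ones((len(features), 1))
        if self.extra_cols:
            exog = np.column_stack(
                [exog, features[list(self.extra_cols)].to_numpy(dtype=float)]
            )
        return np.asarray(self.result.predict(exog=exog, exog_smooth=Xs))


class _SkPredictor:
    def __init__(self, model, feature_cols):
        self.model = model
        self.feature_cols = feature_cols

    def __call__(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_cols].to_numpy(dtype=float)
        proba = self.model.predict_proba(X)
        pos = list(self.model.classes_).index(1)
        return proba[:, pos]


def _train_mask(blocks, held_out, index):
    holdout_cells = set(blocks[held_out].cell_ids)
    return np.array([c not in holdout_cells for c in index])


def _fit_glm(y, features, combo, extra_cols, degrees):
    X = _GLMPredictor.design(features, combo, degrees, extra_cols)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return _GLMPredictor(res, combo, degrees, extra_cols)


def _fit_gam(y, features, combo, extra_cols, gam_df):
    Xs = features[list(combo)].to_numpy(dtype=float)
    smoother = BSplines(Xs, df=[gam_df] * len(combo), degree=[3] * len(combo))
    exog = np.ones((len(features), 1))
    if extra_cols:
        exog = np.column_stack([exog, features[list(extra_cols)].to_numpy(dtype=float)])
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = GLMGam(
                y, exog=exog, smoother=smoother, family=sm.families.Binomial()
            ).fit()
    except Exception as exc:
        # perfectly separable folds break penalised IRLS; a quadratic GLM
        # diverges gracefully and still predicts the separable fold perfectly
        logger.warning("GAM fold failed (%s); falling back to quadratic GLM", exc)
        return _fit_glm(y, features, combo, extra_cols, (2,) * len(combo))
    eps = 1e-9 + 1e-9 * np.abs(Xs).max(axis=0)
    return _GAMPredictor(res, combo, extra_cols, Xs.min(axis=0) + eps, Xs.max(axis=0) - eps)


def _bernoulli_deviance(y, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return -2.0 * float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_sdm(
    species_id: str,
    technique: str,
    combo: tuple[str, ...],
    blocks: list[SamplingBlock],
    presence: np.ndarray,
    features: pd.DataFrame,
    config: SDMConfig | None = None,
) -> list[FittedSDM]:
    """Fit one technique for one species with leave-one-block-out CV.

    ``features`` holds the bioclim (and optionally land-cover) columns
    over the study cells, index-aligned with ``presence``.  Columns not
    in ``combo`` are treated as linear extra features (the climate +
    land-cover variant).  Returns ten fitted models, one per held-out
    block, each carrying its held-out AUC (NaN if the block lacked a
    class, logged as a warning).
    """
    config = config or SDMConfig()
    y_all = np.asarray(presence, dtype=float)
    extra_cols = tuple(c for c in features.columns if c not in combo)
    k = len(blocks)
    masks = [_train_mask(blocks, b, features.index) for b in range(k)]

    def holdout_auc(predictor, b) -> float:
        m = ~masks[b]
        val = auc(predictor(features.loc[m]), y_all[m])
        if np.isnan(val):
            logger.warning(
                "block %d holds a single class for %s: AUC undefined", b + 1, species_id
            )
        return val

    def fit_fold(fit_fn, b):
        m = masks[b]
        y = y_all[m]
        if y.min() == y.max():  # degenerate training fold
            return _ConstantPredictor(float(y.mean()))
        return fit_fn(y, features.loc[m])

    fits: list[FittedSDM] = []

    if technique == "GLM":
        grid_scores = {}
        grid_fits = {}
        for degrees in product(config.glm_degrees, repeat=len(combo)):
            preds = [
                fit_fold(lambda y, f: _fit_glm(y, f, combo, extra_cols, degrees), b)
                for b in range(k)
            ]
            aucs = [holdout_auc(preds[b], b) for b in range(k)]
            grid_scores[degrees] = np.nanmean(aucs)
            grid_fits[degrees] = (preds, aucs)
        best = max(sorted(grid_scores), key=lambda d: (grid_scores[d], tuple(-x for x in d)))
        preds, aucs = grid_fits[best]
        for b in range(k):
            fits.append(
                FittedSDM(species_id, "GLM", b + 1, {"degrees": best}, aucs[b], preds[b])
            )

    elif technique == "GAM":
        for b in range(k):
            pred = fit_fold(
                lambda y, f: _fit_gam(y, f, combo, extra_cols, config.gam_df), b
            )
            fits.append(
                FittedSDM(
                    species_id, "GAM", b + 1, {"df": config.gam_df},
                    holdout_auc(pred, b), pred,
                )
            )

    elif technique == "GBM":
        feature_cols = list(combo) + list(extra_cols)

        def gbm_fit(tc):
            def fn(y, f):
                model = GradientBoostingClassifier(
                    learning_rate=config.gbm_learning_rate,
                    n_estimators=config.gbm_n_trees,
                    max_depth=tc,
                    random_state=config.seed,
                )
                model.fit(f[feature_cols].to_numpy(dtype=float), y.astype(int))
                return _SkPredictor(model, feature_cols)
            return fn

        best_tc, best_err, best_preds = None, np.inf, None
        for tc in config.gbm_tc_range:
            preds = [fit_fold(gbm_fit(tc), b) for b in range(k)]
            err = sum(
                _bernoulli_deviance(y_all[~masks[b]], preds[b](features.loc[~masks[b]]))
                for b in range(k)
            )
            if err < best_err:
                best_tc, best_err, best_preds = tc, err, preds
        for b in range(k):
            fits.append(
                FittedSDM(
                    species_id, "GBM", b + 1,
                    {"tc": best_tc, "lr": config.gbm_learning_rate,
                     "nt": config.gbm_n_trees},
                    holdout_auc(best_preds[b], b), best_preds[b],
                )
            )

    elif technique == "RF":
        feature_cols = list(combo) + list(extra_cols)
        best_key, best_mean, best_preds, best_aucs = None, -np.inf, None, None
        for mtry in config.rf_mtry_range:
            models = []
            for b in range(k):
                m = masks[b]
                y = y_all[m]
                if y.min() == y.max():
                    models.append(_ConstantPredictor(float(y.mean())))
                else:
                    rf = RandomForestClassifier(
                        n_estimators=config.rf_initial_trees,
                        max_features=min(mtry, len(feature_cols)),
                        warm_start=True,
                        random_state=config.seed + b,
                    )
                    rf.fit(features.loc[m, feature_cols].to_numpy(dtype=float),
                           y.astype(int))
                    models.append(_SkPredictor(rf, feature_cols))
            nt = config.rf_initial_trees
            aucs = [holdout_auc(models[b], b) for b in range(k)]
            mean_auc = np.nanmean(aucs)
            if mean_auc > best_mean:
                best_key, best_mean = (mtry, nt), mean_auc
                best_preds, best_aucs = list(models), list(aucs)
            while nt + config.rf_tree_step <= config.rf_max_trees:
                nt += config.rf_tree_step
                for b, pred in enumerate(models):
                    if isinstance(pred, _SkPredictor):
                        pred.model.n_estimators = nt
                        m = masks[b]
                        pred.model.fit(
                            features.loc[m, feature_cols].to_numpy(dtype=float),
                            y_all[m].astype(int),
                        )
                new_aucs = [holdout_auc(models[b], b) for b in range(k)]
                new_mean = np.nanmean(new_aucs)
                if new_mean > best_mean:
                    best_key, best_mean = (mtry, nt), new_mean
                    best_preds, best_aucs = list(models), list(new_aucs)
                if (new_mean - mean_auc) / max(mean_auc, 1e-12) < config.rf_auc_gain_threshold:
                    break
                mean_auc = new_mean
        mtry, nt = best_key
        for b in range(k):
            fits.append(
                FittedSDM(
                    species_id, "RF", b + 1, {"mtry": mtry, "nt": nt},
                    best_aucs[b], best_preds[b],
                )
            )
    else:
        raise ValueError(f"unknown technique {technique!r}")

    return fits


def fit_all_techniques(
    species_id: str,
    combo: tuple[str, ...],
    blocks: list[SamplingBlock],
    presence: np.ndarray,
    features: pd.DataFrame,
    config: SDMConfig | None = None,
) -> list[FittedSDM]:
    """All four techniques x ten blocks = 40 fitted models."""
    fits = []
    for technique in TECHNIQUES:
        fits.extend(
            fit_sdm(species_id, technique, combo, blocks, presence, features, config)
        )
    return fits


# -- ensembles ----------------------------------------------------------


def ensemble_suitability(
    models: list[FittedSDM], features: pd.DataFrame
) -> np.ndarray:
    """Performance-weighted mean prediction, weights max(AUC - 0.5, 0).

    Models with undefined AUC get weight zero; if every weight is zero
    the mean falls back to equal weights with a warning.
    """
    preds = np.stack([m.predict(features) for m in models])
    aucs = np.array([m.auc_holdout for m in models], dtype=float)
    w = np.where(np.isnan(aucs), 0.0, np.maximum(aucs - 0.5, 0.0))
    if w.sum() == 0:
        warnings.warn("all ensemble weights zero; falling back to equal weights")
        w = np.ones(len(models))
    w = w / w.sum()
    return w @ preds


def suitability_surface(
    models: list[FittedSDM],
    features_era1: pd.DataFrame,
    features_era2: pd.DataFrame,
) -> SuitabilitySurface:
    """Median (and weighted-mean) suitability for both windows, plus change."""
    p1 = np.stack([m.predict(features_era1) for m in models])
    p2 = np.stack([m.predict(features_era2) for m in models])
    med1 = np.median(p1, axis=0)
    med2 = np.median(p2, axis=0)
    return SuitabilitySurface(
        species_id=models[0].species_id,
        cell_ids=features_era1.index,
        suitability_era1=med1,
        suitability_era2=med2,
        change=med2 - med1,
        weighted_era1=ensemble_suitability(models, features_era1),
        weighted_era2=ensemble_suitability(models, features_era2),
    )
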