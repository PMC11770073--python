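"""Patient-separated, class-weighted gradient-boosting ensemble for eICP.

Training runs ten patient-level 80/20 shuffle splits. Inside each split the
pulse-shape Isomap and the Spearman-redundancy feature selection are fitted
on the training patients only, a histogram gradient-boosted tree regressor
is fitted with inverse-class-frequency sample weights (classes split at
20 mmHg), and the held-out patients score the fold. The final estimated ICP
(eICP) of a window is the median of the ten fold-model predictions.

The default hyperparameters are 4000 trees, maximum depth 15, L2
regularization 0.5, at most 50 leaf nodes, at least 80 samples per leaf,
learning rate 0.005 and 255 histogram bins; the grid search tunes the number
of trees and the depth by mean held-out MAE.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.model_selection import GroupKFold
from sklearn.utils.validation import check_is_fitted

from .features import (
    PULSE_COLUMN_PREFIX,
    PulseIsomap,
    SpearmanRedundancySelector,
)

HI_ICP_THRESHOLD_MMHG = 20.0
FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    n_trees: int = 4000
    max_depth: int = 15
    l2_regularization: float = 0.5
    max_leaf_nodes: int = 50
    min_samples_leaf: int = 80
    learning_rate: float = 0.005
    n_histogram_bins: int = 255
    grid_n_trees: tuple[int, ...] = (1000, 2000, 4000)
    grid_max_depth: tuple[int, ...] = (5, 10, 15)
    hi_threshold_mmHg: float = HI_ICP_THRESHOLD_MMHG
    n_splits: int = 10
    train_fraction: float = 0.8
    seed: int | None = None
    n_selected_features: int = 15
    redundancy_threshold: float = 0.9
    embed_components: int = 25
    embed_neighbors: int = 10
    strict_group_kfold: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.learning_rate < 1.0):
            raise ValueError("learning_rate must lie in (0, 1)")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")
        for name in ("n_trees", "max_depth", "max_leaf_nodes", "min_samples_leaf",
                     "n_histogram_bins", "n_splits"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def compute_class_weights(
    targets: np.ndarray, hi_threshold: float = HI_ICP_THRESHOLD_MMHG
) -> np.ndarray:
    """Inverse-class-frequency sample weights, w_c = N / (2 * N_c), for the
    two ICP classes split at ``hi_threshold``. The unweighted mean of the
    returned weights is exactly 1, so the effective sample size is unchanged.
    With a single represented class all weights are 1 (with a warning)."""
    targets = np.asarray(targets, dtype=float)
    if targets.size == 0:
        raise ValueError("empty targets")
    hi = targets >= hi_threshold
    n, n_hi = len(targets), int(hi.sum())
    n_lo = n - n_hi
    if n_hi == 0 or n_lo == 0:
        warnings.warn("only one ICP class present; using uniform weights")
        return np.ones(n)
    w = np.where(hi, n / (2.0 * n_hi), n / (2.0 * n_lo))
    return w


def make_patient_splits(
    patient_ids,
    n_splits: int = 10,
    train_fraction: float = 0.8,
    seed: int | None = None,
    strict_group_kfold: bool = False,
) -> list[tuple[list[str], list[str]]]:
    """Patient-level split plan: ``n_splits`` seeded shuffles assigning
    ceil(train_fraction * P) patients to training and the rest to testing.
    ``strict_group_kfold`` instead partitions patients into n_splits folds
    (each patient held out exactly once)."""
    unique = sorted(pd.unique(np.asarray(patient_ids, dtype=object)))
    if len(unique) < 5:
        raise ValueError(f"need >= 5 patients, got {len(unique)}")
    rng = np.random.default_rng(seed)
    plan: list[tuple[list[str], list[str]]] = []
    if strict_group_kfold:
        gkf = GroupKFold(n_splits=n_splits)
        dummy = np.zeros(len(unique))
        for tr, te in gkf.split(dummy, groups=unique):
            plan.append(([unique[i] for i in tr], [unique[i] for i in te]))
    else:
        n_train = int(np.ceil(train_fraction * len(unique)))
        if n_train >= len(unique):
            n_train = len(unique) - 1
        for _ in range(n_splits):
            perm = rng.permutation(len(unique))
            train = sorted(unique[i] for i in perm[:n_train])
            test = sorted(unique[i] for i in perm[n_train:])
            plan.append((train, test))
    for train, test in plan:
        assert not set(train) & set(test), "leakage: patient on both sides of a split"
    covered = set().union(*(set(te) for _, te in plan))
    if covered != set(unique):
        # re-draw uncovered patients into the last test sets deterministically
        missing = sorted(set(unique) - covered)
        for i, pid in enumerate(missing):
            tr, te = plan[i % len(plan)]
            tr = [p for p in tr if p != pid]
            plan[i % len(plan)] = (tr, sorted(te + [pid]))
    return plan


def _split_columns(X: pd.DataFrame) -> tuple[list[str], list[str]]:
    pulse_cols = [c for c in X.columns if c.startswith(PULSE_COLUMN_PREFIX)]
    feat_cols = [c for c in X.columns if c not in pulse_cols]
    return feat_cols, pulse_cols


class IcpEnsembleRegressor(BaseEstimator, RegressorMixin):
    """Median-of-folds histogram-gradient-boosting regressor for eICP.

    Parameters mirror :class:`ModelConfig`. ``fit`` expects a DataFrame whose
    columns are the named morphology features plus the raw mean-pulse shape
    (columns ``pulse_00..pulse_99``), the window-mean invasive ICP as target,
    and the patient identifier of each window as ``groups``.

    Fitted attributes (per fold): ``fold_models_``, ``fold_embeddings_``,
    ``fold_selections_``, plus ``split_plan_`` and ``cv_results_``.
    """

    def __init__(
        self,
        n_trees: int = 4000,
        max_depth: int = 15,
        l2_regularization: float = 0.5,
        max_leaf_nodes: int = 50,
        min_samples_leaf: int = 80,
        learning_rate: float = 0.005,
        n_histogram_bins: int = 255,
        hi_threshold_mmHg: float = HI_ICP_THRESHOLD_MMHG,
        n_splits: int = 10,
        train_fraction: float = 0.8,
        n_selected_features: int = 15,
        redundancy_threshold: float = 0.9,
        embed_components: int = 25,
        embed_neighbors: int = 10,
        strict_group_kfold: bool = False,
        class_weighting: bool = True,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.l2_regularization = l2_regularization
        self.max_leaf_nodes = max_leaf_nodes
        self.min_samples_leaf = min_samples_leaf
        self.learning_rate = learning_rate
        self.n_histogram_bins = n_histogram_bins
        self.hi_threshold_mmHg = hi_threshold_mmHg
        self.n_splits = n_splits
        self.train_fraction = train_fraction
        self.n_selected_features = n_selected_features
        self.redundancy_threshold = redundancy_threshold
        self.embed_components = embed_components
        self.embed_neighbors = embed_neighbors
        self.strict_group_kfold = strict_group_kfold
        self.class_weighting = class_weighting
        self.random_state = random_state

    def _validate(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a DataFrame of named features + pulse columns")
        bad = [c for c in X.columns if not np.all(np.isfinite(X[c].to_numpy(dtype=float)))]
        if bad:
            raise ValueError(f"non-finite values in feature columns: {bad}")
        return X

    def _make_regressor(self, n_trees: int, max_depth: int) -> HistGradientBoostingRegressor:
        return HistGradientBoostingRegressor(
            max_iter=n_trees,
            max_depth=max_depth,
            l2_regularization=self.l2_regularization,
            max_leaf_nodes=self.max_leaf_nodes,
            min_samples_leaf=self.min_samples_leaf,
            learning_rate=self.learning_rate,
            max_bins=self.n_histogram_bins,
            early_stopping=False,
            random_state=0 if self.random_state is None else self.random_state,
        )

    def _fit_fold(self, X, y, train_mask, n_trees, max_depth):
        feat_cols, pulse_cols = _split_columns(X)
        X_tr = X.loc[train_mask]
        y_tr = y[train_mask.to_numpy() if hasattr(train_mask, "to_numpy") else train_mask]
        embedding = PulseIsomap(
            n_components=self.embed_components, n_neighbors=self.embed_neighbors,
            auto_connect=True,
        ).fit(X_tr[pulse_cols].to_numpy())
        iso_tr = pd.DataFrame(
            embedding.transform(X_tr[pulse_cols].to_numpy()),
            columns=embedding.feature_names(), index=X_tr.index,
        )
        cand_tr = pd.concat([X_tr[feat_cols], iso_tr], axis=1)
        selector = SpearmanRedundancySelector(
            k=self.n_selected_features, redundancy_threshold=self.redundancy_threshold
        ).fit(cand_tr, y_tr)
        w = compute_class_weights(y_tr, self.hi_threshold_mmHg) if self.class_weighting \
            else np.ones(len(y_tr))
        model = self._make_regressor(n_trees, max_depth)
        model.fit(selector.transform(cand_tr).to_numpy(), y_tr, sample_weight=w)
        return embedding, selector, model

    def _fold_features(self, X, embedding, selector) -> np.ndarray:
        feat_cols, pulse_cols = _split_columns(X)
        iso = pd.DataFrame(
            embedding.transform(X[pulse_cols].to_numpy()),
            columns=embedding.feature_names(), index=X.index,
        )
        cand = pd.concat([X[feat_cols], iso], axis=1)
        return selector.transform(cand).to_numpy()

    def fit(self, X: pd.DataFrame, y, groups=None, grid_search: bool = False):
        X = self._validate(X)
        y = np.asarray(y, dtype=float)
        if groups is None:
            raise ValueError("patient-separated training requires groups (patient ids)")
        groups = np.asarray(groups, dtype=object)
        if len(X) != len(y) or len(y) != len(groups):
            raise ValueError("X, y and groups must have equal lengths")
        if len(X) < 200:
            raise ValueError("need >= 200 windows for ensemble training")

        self.split_plan_ = make_patient_splits(
            groups, self.n_splits, self.train_fraction,
            seed=self.random_state, strict_group_kfold=self.strict_group_kfold,
        )
        if grid_search:
            best = self._grid_search(X, y, groups)
            self.best_params_ = best
            n_trees, max_depth = best
        else:
            n_trees, max_depth = self.n_trees, self.max_depth

        self.fold_models_, self.fold_embeddings_, self.fold_selections_ = [], [], []
        rows = []
        for fold, (train_ids, test_ids) in enumerate(self.split_plan_):
            assert not set(train_ids) & set(test_ids)
            tr_mask = pd.Series(np.isin(groups, train_ids), index=X.index)
            te_mask = pd.Series(np.isin(groups, test_ids), index=X.index)
            embedding, selector, model = self._fit_fold(X, y, tr_mask, n_trees, max_depth)
            self.fold_embeddings_.append(embedding)
            self.fold_selections_.append(selector)
            self.fold_models_.append(model)
            pred_tr = model.predict(self._fold_features(X.loc[tr_mask], embedding, selector))
            pred_te = model.predict(self._fold_features(X.loc[te_mask], embedding, selector))
            d_tr, d_te = pred_tr - y[tr_mask.to_numpy()], pred_te - y[te_mask.to_numpy()]
            rows.append(
                {
                    "fold": fold + 1,
                    "train_mae": float(np.mean(np.abs(d_tr))),
                    "test_mae": float(np.mean(np.abs(d_te))),
                    "train_mse": float(np.mean(d_tr**2)),
                    "test_mse": float(np.mean(d_te**2)),
                    "n_train": int(tr_mask.sum()),
                    "n_test": int(te_mask.sum()),
                }
            )
        self.cv_results_ = pd.DataFrame(rows)
        self.feature_columns_ = list(X.columns)
        self.n_features_in_ = X.shape[1]
        return self

    def _grid_search(self, X, y, groups) -> tuple[int, int]:
        """Pick (n_trees, max_depth) minimizing mean held-out MAE over the
        split plan; ties resolve to the smaller model."""
        results = {}
        for n_trees in sorted(set(getattr(self, "grid_n_trees", (1000, 2000, 4000)))):
            for max_depth in sorted(set(getattr(self, "grid_max_depth", (5, 10, 15)))):
                maes = []
                for train_ids, test_ids in self.split_plan_:
                    tr = pd.Series(np.isin(groups, train_ids), index=X.index)
                    te = pd.Series(np.isin(groups, test_ids), index=X.index)
                    emb, sel, model = self._fit_fold(X, y, tr, n_trees, max_depth)
                    pred = model.predict(self._fold_features(X.loc[te], emb, sel))
                    maes.append(float(np.mean(np.abs(pred - y[te.to_numpy()]))))
                results[(n_trees, max_depth)] = float(np.mean(maes))
        self.grid_results_ = results
        return min(results, key=lambda k: (results[k], k))

    def predict_folds(self, X: pd.DataFrame) -> np.ndarray:
        """Per-fold predictions, shape (n_windows, n_splits)."""
        check_is_fitted(self, "fold_models_")
        X = self._validate(X)
        if list(X.columns) != self.feature_columns_:
            raise ValueError("feature signature does not match the fitted bundle")
        preds = [
            model.predict(self._fold_features(X, emb, sel))
            for model, emb, sel in zip(
                self.fold_models_, self.fold_embeddings_, self.fold_selections_
            )
        ]
        return np.column_stack(preds)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """eICP = median across the fold models (mean of the two central
        order statistics for an even fold count)."""
        return np.median(self.predict_folds(X), axis=1)


@dataclass
class ModelBundle:
    """Fitted ensemble plus its configuration, for persistence."""

    estimator: IcpEnsembleRegressor
    config: ModelConfig = field(default_factory=ModelConfig)
    format_version: int = FORMAT_VERSION

    def save(self, path: str | Path) -> None:
        path = Path(path)
        joblib.dump(self, path)
        sidecar = {
            "format_version": self.format_version,
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(self.config).items()},
            "selected_features": [
                s.selected_names_ for s in self.estimator.fold_selections_
            ],
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @staticmethod
    def load(path: str | Path) -> "ModelBundle":
        return joblib.load(path)


def train_ensemble(
    features: pd.DataFrame,
    targets,
    patient_ids,
    config: ModelConfig | None = None,
    do_grid_search: bool = False,
) -> ModelBundle:
    """Fit the ten-fold class-weighted ensemble on a per-window feature table."""
    config = config if config is not None else ModelConfig()
    est = IcpEnsembleRegressor(
        n_trees=config.n_trees,
        max_depth=config.max_depth,
        l2_regularization=config.l2_regularization,
        max_leaf_nodes=config.max_leaf_nodes,
        min_samples_leaf=config.min_samples_leaf,
        learning_rate=config.learning_rate,
        n_histogram_bins=config.n_histogram_bins,
        hi_threshold_mmHg=config.hi_threshold_mmHg,
        n_splits=config.n_splits,
        train_fraction=config.train_fraction,
        n_selected_features=config.n_selected_features,
        redundancy_threshold=config.redundancy_threshold,
        embed_components=config.embed_components,
        embed_neighbors=config.embed_neighbors,
        strict_group_kfold=config.strict_group_kfold,
        random_state=config.seed,
    )
    est.grid_n_trees = config.grid_n_trees
    est.grid_max_depth = config.grid_max_depth
    est.fit(features, targets, groups=patient_ids, grid_search=do_grid_search)
    return ModelBundle(estimator=est, config=config)


def predict_eicp(
    bundle: ModelBundle | IcpEnsembleRegressor,
    features: pd.DataFrame,
    window_ids=None,
    patient_ids=None,
    reference_icp=None,
) -> pd.DataFrame:
    """Prediction records: one row per window with the per-fold predictions
    and their median (eICP)."""
    est = bundle.estimator if isinstance(bundle, ModelBundle) else bundle
    folds = est.predict_folds(features)
    out = pd.DataFrame(
        {
            "window_id": window_ids if window_ids is not None else np.arange(len(folds)),
            "patient_id": patient_ids if patient_ids is not None else "",
            "eicp_mmHg": np.median(folds, axis=1),
        }
    )
    if reference_icp is not None:
        out["reference_icp_mmHg"] = np.asarray(reference_icp, dtype=float)
    for j in range(folds.shape[1]):
        out[f"fold_{j + 1}"] = folds[:, j]
    return out
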