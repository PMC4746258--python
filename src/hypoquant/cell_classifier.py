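"""Random-Forest cell-type classification with per-cell confidence scores.

The forest is Breiman's original recipe — bagged decision trees, each split
drawn from a random √p feature subset — built from scikit-learn's
``BaggingClassifier`` over ``DecisionTreeClassifier`` so that every tree's
bootstrap sample is accessible, which makes out-of-bag (OOB) permutation
importance and per-tree vote counting exact.  Features enter untransformed
(no scaling or normalisation).  A cell's confidence is the fraction of trees
voting for its winning class, used downstream for 50/70/90 % filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.tree import DecisionTreeClassifier

from .morphometrics import FEATURE_NAMES, canonical_feature_name

logger = logging.getLogger(__name__)

#: Default feature subset: all 22 features except the Cartesian coordinates,
#: which carry no information in a radially symmetric organ.
DEFAULT_FEATURES_18 = tuple(
    f for f in FEATURE_NAMES if f not in ("m.cx", "m.cy", "Xnew", "Ynew")
)

#: Highest-ranked features, the seed of a reduced 5-feature subset.
FIVE_FEATURE_SEED = ("radialV", "MedianROIW", "MedianROIC", "s.area")


def select_feature_subset(
    base: tuple[str, ...] | list[str] = DEFAULT_FEATURES_18,
    drop: list[str] | None = None,
) -> tuple[str, ...]:
    """Reduced feature subset: *base* minus user-marked redundant features."""
    drop_set = {canonical_feature_name(f) for f in (drop or [])}
    return tuple(canonical_feature_name(f) for f in base if canonical_feature_name(f) not in drop_set)


@dataclass
class ClassifierModel:
    """Fitted forest plus everything needed to reproduce its predictions."""

    forest: BaggingClassifier
    feature_subset: tuple[str, ...]
    class_names: tuple[str, ...]
    importances: pd.Series          # OOB permutation importance
    impurity_importances: pd.Series  # mean impurity-based importance, for comparison
    n_trees: int
    seed: int
    oob_score: float
    iteration_id: str | None = None

    def save(self, path) -> None:
        import joblib

        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ClassifierModel":
        import joblib

        return joblib.load(path)


def _resolve_annotations(
    tables: pd.DataFrame | dict[str, pd.DataFrame], annotations: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Join annotation rows (image_id, cell_id, class_label) onto feature rows."""
    required = {"cell_id", "class_label"}
    if not required.issubset(annotations.columns):
        raise ValueError(f"annotations need columns {sorted(required)}")
    if isinstance(tables, pd.DataFrame):
        tables = {"__single__": tables}
    dup = annotations.duplicated(subset=[c for c in ("image_id", "cell_id") if c in annotations])
    if dup.any():
        raise ValueError("duplicate (image_id, cell_id) annotations")
    rows, labels = [], []
    for _, ann in annotations.iterrows():
        image_id = ann.get("image_id", "__single__")
        if image_id not in tables:
            raise KeyError(f"annotation references unknown image {image_id!r}")
        table = tables[image_id]
        cid = ann["cell_id"]
        if cid not in table.index:
            raise KeyError(f"annotation references unknown cell {cid!r} in {image_id!r}")
        rows.append(table.loc[cid])
        labels.append(ann["class_label"])
    return pd.DataFrame(rows).reset_index(drop=True), pd.Series(labels, name="class_label")


def _oob_masks(forest: BaggingClassifier, n_samples: int) -> list[np.ndarray]:
    """Boolean out-of-bag mask per tree (True = sample not in the bootstrap)."""
    masks = []
    for sample_idx in forest.estimators_samples_:
        m = np.ones(n_samples, dtype=bool)
        m[sample_idx] = False
        masks.append(m)
    return masks


def _oob_permutation_importance(
    forest: BaggingClassifier, X: np.ndarray, y: np.ndarray, seed: int
) -> np.ndarray:
    """Mean over trees of the OOB error increase after permuting each feature.

    Trees inside the bagger predict encoded class indices, so *y* is encoded
    to indices of ``forest.classes_`` before comparison.
    """
    n_samples, n_features = X.shape
    class_index = {c: i for i, c in enumerate(forest.classes_)}
    y = np.asarray([class_index[v] for v in y])
    rng = np.random.default_rng(seed)
    deltas = np.zeros(n_features)
    n_used = 0
    for tree, oob in zip(forest.estimators_, _oob_masks(forest, n_samples)):
        if not oob.any():
            continue
        X_oob, y_oob = X[oob], y[oob]
        base_err = np.mean(tree.predict(X_oob) != y_oob)
        perm = rng.permutation(X_oob.shape[0])
        for j in range(n_features):
            X_perm = X_oob.copy()
            X_perm[:, j] = X_oob[perm, j]
            deltas[j] += np.mean(tree.predict(X_perm) != y_oob) - base_err
        n_used += 1
    return deltas / max(n_used, 1)


def train_random_forest(
    tables: pd.DataFrame | dict[str, pd.DataFrame],
    annotations: pd.DataFrame,
    feature_subset: list[str] | tuple[str, ...] | None = None,
    n_trees: int = 500,
    seed: int = 0,
    class_names: list[str] | None = None,
) -> ClassifierModel:
    """Fit the forest on annotated cells, untransformed feature values.

    *tables* is a feature table (or image_id → table mapping), *annotations*
    a frame with ``image_id`` (optional for a single table), ``cell_id`` and
    ``class_label``.  *class_names*, when given, is the full user-defined
    class list; any listed class with zero annotated cells is an error.
    """
    subset = tuple(canonical_feature_name(f) for f in (feature_subset or DEFAULT_FEATURES_18))
    if len(subset) < 1:
        raise ValueError("feature subset must contain at least one feature")
    X_df, y = _resolve_annotations(tables, annotations)
    missing = [f for f in subset if f not in X_df.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    observed = sorted(y.unique())
    if class_names is not None:
        absent = sorted(set(class_names) - set(observed))
        if absent:
            raise ValueError(f"classes with no annotated cells: {absent}")
        classes = tuple(class_names)
    else:
        classes = tuple(observed)
    if len(classes) < 2:
        raise ValueError("need at least two annotated classes")

    X = X_df[list(subset)].to_numpy(dtype=float)
    y_arr = y.to_numpy()
    forest = BaggingClassifier(
        estimator=DecisionTreeClassifier(max_features="sqrt"),
        n_estimators=n_trees,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y_arr)
    oob_imp = _oob_permutation_importance(forest, X, y_arr, seed)
    impurity = np.mean([t.feature_importances_ for t in forest.estimators_], axis=0)
    return ClassifierModel(
        forest=forest,
        feature_subset=subset,
        class_names=classes,
        importances=pd.Series(oob_imp, index=list(subset), name="oob_permutation_importance"),
        impurity_importances=pd.Series(impurity, index=list(subset), name="impurity_importance"),
        n_trees=n_trees,
        seed=seed,
        oob_score=float(forest.oob_score_),
    )


def rank_feature_importance(model: ClassifierModel) -> list[tuple[str, float]]:
    """Features in descending importance; ties keep the canonical feature order."""
    s = model.importances
    order = sorted(range(len(s)), key=lambda i: (-s.iloc[i], i))  # stable: subset order
    return [(s.index[i], float(s.iloc[i])) for i in order]


def predict_with_confidence(model: ClassifierModel, table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell winning class and vote-fraction confidence for every cell.

    Confidence = fraction of trees voting the winning class (ties resolve to
    the first class in the model's class order).  No filtering here.
    """
    missing = [f for f in model.feature_subset if f not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    X = table[list(model.feature_subset)].to_numpy(dtype=float)
    classes = list(model.forest.classes_)
    votes = np.zeros((X.shape[0], len(classes)), dtype=int)
    idx = np.arange(X.shape[0])
    for tree in model.forest.estimators_:
        # trees predict encoded indices into forest.classes_
        pred = tree.predict(X).astype(int)
        votes[idx, pred] += 1
    win = votes.argmax(axis=1)  # first-class tie-break
    conf = votes[np.arange(len(win)), win] / model.n_trees
    return pd.DataFrame(
        {
            "cell_id": table.index.to_numpy(),
            "class_label": [classes[i] for i in win],
            "confidence": conf,
        }
    )


def filter_by_confidence(preds: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Retain cells whose confidence is at least *threshold* (a fraction in [0, 1])."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must be in [0, 1]")
    return preds[preds["confidence"] >= threshold].reset_index(drop=True)
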