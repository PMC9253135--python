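"""Random-forest classification of object tables with OOB evaluation.

The ensemble machinery is scikit-learn's RandomForestClassifier; this
module owns the configuration mapping (number of trees, mtry = floor(p/3)
candidate features per split), the out-of-bag error and confusion
accounting, and the two variable-importance indices:

* mean decrease in accuracy (MDA): for each tree, accuracy on its own
  out-of-bag samples minus accuracy after permuting one feature among
  those samples, averaged over trees — the classical permutation index;
* mean decrease in Gini impurity: split-impurity reduction summed over
  the forest (scikit-learn's impurity importance).

The hierarchy attribute (``super_class``) is a categorical feature and is
one-hot encoded before training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "RFConfig",
    "RFResult",
    "encode_features",
    "train_evaluate",
    "predict",
    "predict_oob",
    "importance_report",
]

CATEGORICAL_COLUMNS = ("super_class",)


@dataclass(frozen=True)
class RFConfig:
    """Forest size, mtry and seed.  mtry=None means floor(p / 3)."""

    n_trees: int = 250
    mtry: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def resolve_mtry(self, p: int) -> int:
        if self.mtry is not None:
            if not 1 <= self.mtry <= p:
                raise ValueError(f"mtry must lie in [1, {p}]")
            return self.mtry
        return max(1, p // 3)


@dataclass
class RFResult:
    """OOB error, OOB confusion matrix, importances and the fitted model."""

    oob_error: float
    confusion: pd.DataFrame
    importance_mda: pd.Series
    importance_gini: pd.Series
    config: RFConfig
    classes_: np.ndarray
    feature_names: list[str]
    model: RandomForestClassifier


def encode_features(table: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix: one-hot encode the categorical columns.

    Dummy columns are emitted in sorted category order so the encoding is
    deterministic regardless of row order.
    """
    out = table
    for col in CATEGORICAL_COLUMNS:
        if col in out.columns:
            cats = np.sort(out[col].unique())
            dummies = pd.DataFrame(
                {f"{col}={c}": (out[col] == c).astype(float) for c in cats},
                index=out.index,
            )
            out = pd.concat([out.drop(columns=[col]), dummies], axis=1)
    return out.astype(float)


def train_evaluate(
    table: pd.DataFrame, labels: pd.Series | np.ndarray, config: RFConfig | None = None
) -> RFResult:
    """Fit the forest and evaluate it out-of-bag.

    Every sample's OOB prediction comes only from trees whose bootstrap
    excluded it; the OOB error is the fraction of samples whose OOB
    prediction disagrees with the label.
    """
    config = config or RFConfig()
    x = encode_features(table)
    if x.isna().any().any():
        raise ValueError("feature table contains missing values")
    y = np.asarray(labels)
    if x.shape[0] != y.shape[0]:
        raise ValueError("labels length must match table rows")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("at least two classes required")
    p = x.shape[1]
    mtry = config.resolve_mtry(p)

    clf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=mtry,
        bootstrap=True,
        oob_score=True,
        random_state=config.seed,
        n_jobs=1,
    )
    # fit on encoded labels 0..k-1 so per-tree predictions compare directly
    y_enc = np.searchsorted(classes, y)
    xv = x.to_numpy()
    clf.fit(xv, y_enc)

    votes = clf.oob_decision_function_
    has_vote = votes.sum(axis=1) > 0
    pred_enc = np.zeros(y_enc.shape, dtype=np.int64)
    pred_enc[has_vote] = np.argmax(votes[has_vote], axis=1)
    correct = pred_enc == y_enc
    # samples never out-of-bag (essentially unreachable at 250 trees) -> error
    correct[~has_vote] = False
    oob_error = float(1.0 - correct.mean())

    pred = classes[pred_enc]
    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(pred, name="oob_pred")
    ).reindex(index=classes, columns=classes, fill_value=0)

    mda = _mean_decrease_accuracy(clf, xv, y_enc, seed=config.seed)
    result = RFResult(
        oob_error=oob_error,
        confusion=confusion,
        importance_mda=pd.Series(mda, index=x.columns, name="mda"),
        importance_gini=pd.Series(
            clf.feature_importances_, index=x.columns, name="gini"
        ),
        config=config,
        classes_=classes,
        feature_names=list(x.columns),
        model=clf,
    )
    return result


def predict(result: RFResult, table: pd.DataFrame) -> np.ndarray:
    """Standard (in-bag) forest predictions, in original class codes."""
    x = encode_features(table)
    x = x.reindex(columns=result.feature_names, fill_value=0.0)
    return result.classes_[result.model.predict(x.to_numpy()).astype(int)]


def predict_oob(result: RFResult) -> np.ndarray:
    """OOB predictions for the training samples, in original class codes."""
    votes = result.model.oob_decision_function_
    return result.classes_[np.argmax(votes, axis=1)]


def _mean_decrease_accuracy(
    clf: RandomForestClassifier, x: np.ndarray, y: np.ndarray, seed: int
) -> np.ndarray:
    """Per-tree OOB permutation importance, averaged over trees."""
    rng = np.random.default_rng(seed)
    n, p = x.shape
    decreases = np.zeros(p)
    n_used = 0
    for tree, in_bag in zip(clf.estimators_, clf.estimators_samples_):
        oob = np.ones(n, dtype=bool)
        oob[in_bag] = False
        if not oob.any():
            continue
        n_used += 1
        x_oob = x[oob]
        y_oob = y[oob]
        base = np.mean(tree.predict(x_oob) == y_oob)
        m = x_oob.shape[0]
        for j in range(p):
            perm = rng.permutation(m)
            x_perm = x_oob.copy()
            x_perm[:, j] = x_oob[perm, j]
            decreases[j] += base - np.mean(tree.predict(x_perm) == y_oob)
    return decreases / max(n_used, 1)


def importance_report(
    result: RFResult, top_k: int | None = None
) -> dict[str, list[tuple[str, float]]]:
    """Ranked (feature, score) lists for both indices.

    Descending score; ties broken by feature name so the ranking is
    deterministic.  ``top_k`` beyond p is truncated to p.
    """
    p = len(result.feature_names)
    k = p if top_k is None else min(top_k, p)
    out = {}
    for name, series in (
        ("mda", result.importance_mda),
        ("gini", result.importance_gini),
    ):
        order = sorted(series.items(), key=lambda kv: (-kv[1], kv[0]))
        out[name] = [(f, float(s)) for f, s in order[:k]]
    return out
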