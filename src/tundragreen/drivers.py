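"""Random-forest attribution of trend classes to environmental drivers.

The class distribution is heavily skewed (browning is rare), so the
data set is first balanced down to the browning count per class, then
highly correlated predictors (|r| > 0.75) are screened out by
iteratively removing the member of the worst pair with the highest
mean absolute correlation.  A random-forest classifier is tuned by
out-of-bag accuracy over the per-node feature count, evaluated on a
withheld third of the rows, and interrogated with permutation
(mean-decrease-in-accuracy) importance and per-class partial
dependence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

logger = logging.getLogger(__name__)

__all__ = ["DriverDataset", "FittedClassifier", "prepare_dataset",
           "screen_correlated", "fit_classifier", "variable_importance",
           "partial_dependence"]


@dataclass
class DriverDataset:
    X: pd.DataFrame
    y: pd.Series
    screened_out: tuple
    class_count: int


@dataclass
class FittedClassifier:
    model: RandomForestClassifier
    mtry: int
    oob_accuracy: float
    accuracy: float
    class_accuracy: dict
    feature_names: tuple
    X_eval: pd.DataFrame = None
    y_eval: pd.Series = None


def screen_correlated(X: pd.DataFrame, threshold: float = 0.75):
    """Iteratively drop one of each |r| > threshold predictor pair.

    While any pair exceeds the threshold, the member of the offending
    pairs with the highest mean absolute correlation against all other
    remaining predictors is removed.  Returns (kept frame, removed names).
    """
    cols = list(X.columns)
    removed = []
    while len(cols) > 1:
        corr = X[cols].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        if corr.values.max() <= threshold:
            break
        # candidates: every column in at least one offending pair
        offenders = corr.index[(corr > threshold).any(axis=1)]
        mean_abs = corr.loc[offenders].mean(axis=1)
        drop = mean_abs.sort_values(ascending=False, kind="stable").index[0]
        removed.append(drop)
        cols.remove(drop)
    return X[cols], tuple(removed)


def prepare_dataset(classes: pd.Series, driver_table: pd.DataFrame, rng,
                    min_class_size: int = 5,
                    corr_threshold: float = 0.75) -> DriverDataset:
    """Balanced, screened classifier input.

    ``classes`` maps site_id -> trend class; ``driver_table`` has a
    site_id column plus predictors.  The rarest class (browning in
    practice) sets the per-class sample size; the same number of rows
    is drawn at random from every other class.  Correlation screening
    runs on the balanced table, after balancing, mirroring the
    analysis order.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    df = driver_table.merge(classes.rename("trend_class"), left_on="site_id",
                            right_index=True, how="inner")
    counts = df["trend_class"].value_counts()
    n_min = int(counts.min())
    floor_class = counts.idxmin()
    if n_min < min_class_size:
        raise ValueError(
            f"class {floor_class!r} has {n_min} sites, below the floor of "
            f"{min_class_size}; cannot balance")
    picks = []
    for cls, g in df.groupby("trend_class", sort=True):
        idx = rng.choice(g.index.to_numpy(), size=n_min, replace=False)
        picks.append(np.sort(idx))
    bal = df.loc[np.concatenate(picks)].reset_index(drop=True)
    predictors = [c for c in driver_table.columns if c != "site_id"]
    X, removed = screen_correlated(bal[predictors], corr_threshold)
    if removed:
        logger.info("screened out correlated predictors: %s", list(removed))
    return DriverDataset(X=X, y=bal["trend_class"], screened_out=removed,
                         class_count=n_min)


def fit_classifier(dataset: DriverDataset, rng, n_estimators: int = 500,
                   train_fraction: float = 2.0 / 3.0,
                   mtry_grid=None) -> FittedClassifier:
    """Tuned random forest with honest withheld-third accuracy.

    The per-node feature count (mtry) is tuned to maximise out-of-bag
    accuracy on the training two-thirds; the reported overall and
    per-class accuracies come only from the withheld third.
    """
    if dataset.y.nunique() < 2:
        raise ValueError("degenerate single-class data; cannot fit classifier")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    n = len(dataset.y)
    perm = rng.permutation(n)
    n_train = int(round(train_fraction * n))
    tr, te = perm[:n_train], perm[n_train:]
    Xtr, ytr = dataset.X.iloc[tr], dataset.y.iloc[tr]
    Xte, yte = dataset.X.iloc[te], dataset.y.iloc[te]

    p = dataset.X.shape[1]
    if mtry_grid is None:
        default = max(1, int(round(np.sqrt(p))))
        mtry_grid = sorted({max(1, default // 2), default, min(p, default * 2)})
    best = None
    for mtry in mtry_grid:
        clf = RandomForestClassifier(n_estimators=n_estimators, max_features=mtry,
                                     oob_score=True, bootstrap=True,
                                     random_state=int(rng.integers(2**31)))
        clf.fit(Xtr, ytr)
        if best is None or clf.oob_score_ > best[1]:
            best = (clf, clf.oob_score_, mtry)
    model, oob, mtry = best
    pred = model.predict(Xte)
    acc = float(np.mean(pred == yte.to_numpy()))
    per_class = {}
    for cls in sorted(dataset.y.unique()):
        mask = yte.to_numpy() == cls
        per_class[cls] = float(np.mean(pred[mask] == cls)) if mask.any() else float("nan")
    return FittedClassifier(model=model, mtry=mtry, oob_accuracy=float(oob),
                            accuracy=acc, class_accuracy=per_class,
                            feature_names=tuple(dataset.X.columns),
                            X_eval=Xte, y_eval=yte)


def variable_importance(fitted: FittedClassifier, rng=None,
                        n_repeats: int = 10) -> pd.Series:
    """Mean decrease in accuracy under predictor permutation.

    Each predictor column of the evaluation set is shuffled
    ``n_repeats`` times; the importance is the mean drop in withheld
    accuracy, sorted descending.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    X, y = fitted.X_eval, fitted.y_eval.to_numpy()
    base = np.mean(fitted.model.predict(X) == y)
    scores = {}
    for col in fitted.feature_names:
        drops = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[col] = rng.permutation(Xp[col].to_numpy())
            drops.append(base - np.mean(fitted.model.predict(Xp) == y))
        scores[col] = float(np.mean(drops))
    return pd.Series(scores).sort_values(ascending=False)


def partial_dependence(fitted: FittedClassifier, dataset: DriverDataset,
                       predictor: str, grid=None, n_grid: int = 20,
                       fix_at_mean: bool = False) -> pd.DataFrame:
    """Per-class classification probability across one predictor's range.

    By default the probabilities are averaged over the empirical
    distribution of the other predictors (the standard partial
    dependence estimator); with ``fix_at_mean`` the other predictors
    are literally held at their means.  Probabilities sum to one at
    every grid point.
    """
    if predictor not in dataset.X.columns:
        raise KeyError(f"unknown predictor {predictor!r}")
    if grid is None:
        grid = np.linspace(dataset.X[predictor].min(), dataset.X[predictor].max(), n_grid)
    classes = list(fitted.model.classes_)
    rows = []
    if fix_at_mean:
        base = dataset.X.mean().to_frame().T
        for v in grid:
            X = base.copy()
            X[predictor] = v
            proba = fitted.model.predict_proba(X[list(fitted.feature_names)])[0]
            rows.append([v] + list(proba))
    else:
        X = dataset.X.copy()
        for v in grid:
            X[predictor] = v
            proba = fitted.model.predict_proba(X[list(fitted.feature_names)]).mean(axis=0)
            rows.append([v] + list(proba))
    return pd.DataFrame(rows, columns=[predictor] + classes)
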