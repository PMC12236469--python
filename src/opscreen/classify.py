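"""Per-variant distinguishability classifiers and clinical ROC procedures.

Each variant gets a binary gradient-boosted classifier separating its single
cells from wild-type cells on the selected image features; the held-out test
AUROC is that variant's distinguishability score.  A variant with a large
morphological effect is easy to separate (AUROC near 1); a wild-type-like
variant is not (AUROC near 0.5).  Zero-shot ROC scores a single continuous
variant-level quantity against binary clinical labels, and the multiclass
procedure trains a linear support-vector classifier on landmark features and
macro-averages one-vs-rest ROC curves with equal class weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AurocScore:
    variant: str
    auroc: float | None
    n_variant_cells: int
    n_wt_cells: int
    split_seed: int
    skipped_reason: str | None = None


def _stratified_811(y: np.ndarray, seed: int):
    """Index arrays of a stratified 8:1:1 train/validation/test split."""
    from sklearn.model_selection import train_test_split

    idx = np.arange(len(y))
    train, rest = train_test_split(idx, test_size=0.2, stratify=y[idx],
                                   random_state=seed)
    val, test = train_test_split(rest, test_size=0.5, stratify=y[rest],
                                 random_state=seed + 1)
    return train, val, test


def variant_auroc(variant_cells: pd.DataFrame, wt_cells: pd.DataFrame,
                  features: list[str], variant: str = "variant",
                  min_cells: int = 150, seed: int = 0,
                  wt_cap_factor: int = 10, n_estimators: int = 800,
                  max_depth: int = 3, learning_rate: float = 0.05,
                  early_stopping_rounds: int = 50,
                  ) -> AurocScore:
    """Held-out AUROC of a gradient-boosted variant-vs-WT classifier.

    Variants with fewer than ``min_cells`` cells are skipped with a reason.
    WT cells are subsampled to at most ``wt_cap_factor`` times the variant
    count so the negative class cannot swamp training.  The data are split
    stratified 8:1:1; training stops early on validation log-loss and the
    AUROC is computed on the untouched test stratum.  Defaults use shallow
    trees and a slow learning rate: morphology-style tabular features with
    modest effect sizes reward regularization over depth.
    """
    from sklearn.metrics import roc_auc_score
    from xgboost import XGBClassifier

    nv = len(variant_cells)
    if nv < min_cells:
        return AurocScore(variant, None, nv, len(wt_cells), seed,
                          skipped_reason=f"fewer than {min_cells} cells")
    rng = np.random.default_rng(seed)
    if len(wt_cells) > wt_cap_factor * nv:
        wt_cells = wt_cells.iloc[rng.choice(len(wt_cells), wt_cap_factor * nv,
                                            replace=False)]
    X = np.concatenate([variant_cells[features].to_numpy(dtype=float),
                        wt_cells[features].to_numpy(dtype=float)])
    y = np.concatenate([np.ones(nv), np.zeros(len(wt_cells))])
    train, val, test = _stratified_811(y, seed)
    if min(y[s].sum() for s in (train, val, test)) == 0:
        raise ValueError("a split stratum has no positive examples")
    clf = XGBClassifier(n_estimators=n_estimators, max_depth=max_depth,
                        learning_rate=learning_rate, eval_metric="logloss",
                        early_stopping_rounds=early_stopping_rounds,
                        random_state=seed, n_jobs=1, verbosity=0)
    clf.fit(X[train], y[train], eval_set=[(X[val], y[val])], verbose=False)
    scores = clf.predict_proba(X[test])[:, 1]
    # bookkeeping guarantee: test indices never intersect train/validation
    assert not (set(test) & (set(train) | set(val)))
    return AurocScore(variant, float(roc_auc_score(y[test], scores)),
                      nv, len(wt_cells), seed)


def zero_shot_roc(scores, labels) -> tuple[pd.DataFrame, float]:
    """Threshold-free ROC of one continuous score against binary labels.

    Returns the ROC curve points and the AUC, which equals the Mann-Whitney
    U statistic normalized by n1*n0 (rank-average tie handling).
    """
    from sklearn.metrics import roc_curve, roc_auc_score

    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise ValueError("both classes must be non-empty")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auc


def multiclass_macro_roc(X: np.ndarray, labels, seed: int = 0, cv: int = 5,
                         fit_on_all: bool = False
                         ) -> tuple[pd.DataFrame, float, dict]:
    """Macro-averaged one-vs-rest ROC of a linear SVC on landmark features.

    Decision scores are cross-validated (stratified ``cv`` folds) so the
    macro ROC is out-of-sample; ``fit_on_all`` switches to in-sample scores.
    The macro curve is the unweighted mean of per-class sensitivity on a
    common specificity grid, weighting every class equally.
    """
    from sklearn.svm import LinearSVC
    from sklearn.preprocessing import StandardScaler
    from sklearn.pipeline import make_pipeline
    from sklearn.model_selection import StratifiedKFold, cross_val_predict
    from sklearn.metrics import roc_curve, auc as sk_auc

    y = np.asarray(labels)
    classes = np.unique(y)
    if len(classes) < 3:
        raise ValueError("need at least 3 classes")
    for c in classes:
        if (y == c).sum() < 3:
            raise ValueError(f"class {c!r} has fewer than 3 members")
    X = np.asarray(X, dtype=float)
    model = make_pipeline(StandardScaler(), LinearSVC())
    if fit_on_all:
        scores = model.fit(X, y).decision_function(X)
    else:
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=seed)
        scores = cross_val_predict(model, X, y, cv=skf,
                                   method="decision_function")
    grid = np.linspace(0, 1, 101)
    per_class_auc = {}
    tprs = []
    for k, c in enumerate(classes):
        fpr, tpr, _ = roc_curve((y == c).astype(int), scores[:, k])
        per_class_auc[str(c)] = float(sk_auc(fpr, tpr))
        tprs.append(np.interp(grid, fpr, tpr))
    macro_tpr = np.mean(tprs, axis=0)
    macro_auc = float(np.trapezoid(macro_tpr, grid))
    curve = pd.DataFrame({"fpr": grid, "tpr": macro_tpr})
    return curve, macro_auc, per_class_auc


def auroc_table(cells: pd.DataFrame, features: list[str], wt_label: str = "WT",
                min_cells: int = 150, seed: int = 0) -> pd.DataFrame:
    """variant_auroc for every non-WT variant, re-split per variant."""
    wt = cells[cells["variant"] == wt_label]
    rows = []
    for i, (variant, grp) in enumerate(
            cells[cells["variant"] != wt_label].groupby("variant", sort=True)):
        res = variant_auroc(grp, wt, features, variant=variant,
                            min_cells=min_cells, seed=seed + i)
        rows.append({"variant": variant, "auroc": res.auroc,
                     "n_variant_cells": res.n_variant_cells,
                     "n_wt_cells": res.n_wt_cells,
                     "skipped_reason": res.skipped_reason})
    return pd.DataFrame(rows).set_index("variant")
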