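"""Cell-type-level predictive modelling on latent-variable scores.

For each cell type the few most strongly associated interpretable LVs
(at most four) form a compact feature set; a classifier on those features
measures how much outcome information the cell type carries.  Performance
is estimated by stratified 10-fold cross-validation repeated 10 times,
with out-of-fold predictions pooled within each repetition into one AUROC
per repetition (mean ± SD reported across repetitions).  Feature
contributions are quantified with exact Shapley values over all feature
coalitions, which is tractable because the feature sets are tiny.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import factorial

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .association import AssociationTable

MAX_EXACT_FEATURES = 12


@dataclass
class CellTypeLVSet:
    cell_type: str
    lvs: list
    ranking_scores: list

    def __post_init__(self) -> None:
        if len(self.lvs) != len(self.ranking_scores):
            raise ValueError("lvs and ranking_scores must align")


def extract_celltype_lvs(table: AssociationTable, cell_type: str, max_n: int = 4) -> CellTypeLVSet:
    """The ``max_n`` interpretable LVs most associated with a cell type,
    ranked by their best passing AUC (ties: lower FDR, then higher weight)."""
    from .association import label_lvs

    labels = label_lvs(table)
    best: dict = {}
    for r in table.records:
        if not r.passes or labels.get(r.lv) != cell_type:
            continue
        key = (-r.auc, r.fdr, -r.u_weight)
        if r.lv not in best or key < best[r.lv]:
            best[r.lv] = key
    if not best:
        raise ValueError(f"no interpretable LV labelled {cell_type!r}")
    ranked = sorted(best.items(), key=lambda kv: (kv[1], kv[0]))[:max_n]
    return CellTypeLVSet(
        cell_type=cell_type,
        lvs=[lv for lv, _ in ranked],
        ranking_scores=[-key[0] for _, key in ranked],
    )


@dataclass
class CVResult:
    per_repetition_auroc: list
    mean_auroc: float
    sd_auroc: float
    pooled_predictions: list = field(default_factory=list, repr=False)


def _build_model(model_spec, seed: int):
    if model_spec is None or model_spec == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if model_spec == "logistic":
        return make_pipeline(
            StandardScaler(), LogisticRegression(random_state=seed, max_iter=1000)
        )
    est = clone(model_spec)
    if "random_state" in est.get_params():
        est.set_params(random_state=seed)
    return est


def _scores(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def repeated_cv_auroc(
    X, y, folds: int = 10, repeats: int = 10, model_spec=None, seed: int = 0
) -> CVResult:
    """Repeated stratified k-fold cross-validated AUROC.

    Each repetition draws a fresh stratified fold assignment, fits one
    model per fold and pools the out-of-fold prediction scores; the AUROC
    is computed once per repetition on the pooled scores, and the mean and
    standard deviation are taken across repetitions.  ``model_spec`` is
    "random_forest" (default, library-default hyperparameters),
    "logistic", or any sklearn classifier instance to clone.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    if np.bincount(y_idx).min() < folds:
        raise ValueError(
            f"smallest class has fewer than folds={folds} samples; "
            "every fold needs at least one sample per class"
        )
    rng = np.random.default_rng(seed)
    aurocs, pooled = [], []
    for _ in range(repeats):
        rep_seed = int(rng.integers(2**31 - 1))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rep_seed)
        oof = np.empty(len(y), dtype=float)
        for f, (train, test) in enumerate(skf.split(X, y_idx)):
            model = _build_model(model_spec, seed=rep_seed + f)
            model.fit(X[train], y_idx[train])
            oof[test] = _scores(model, X[test])
        aurocs.append(float(roc_auc_score(y_idx, oof)))
        pooled.append(oof)
    mean = float(np.mean(aurocs))
    sd = float(np.std(aurocs, ddof=1)) if repeats > 1 else 0.0
    return CVResult(aurocs, mean, sd, pooled)


@dataclass
class AttributionMatrix:
    values: np.ndarray  # samples × features Shapley values
    baseline: float
    feature_importance: np.ndarray  # per-feature mean |value|
    feature_names: list = field(default_factory=list)

    def ranking(self) -> list:
        """Features by decreasing mean absolute Shapley value."""
        order = np.argsort(-self.feature_importance, kind="stable")
        names = self.feature_names or list(range(len(self.feature_importance)))
        return [names[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        cols = self.feature_names or list(range(self.values.shape[1]))
        return pd.DataFrame(self.values, columns=cols)


def shapley_attribution(model_fn, X, background, feature_names=None) -> AttributionMatrix:
    """Exact Shapley attribution of ``model_fn`` predictions.

    The coalition value of a feature subset S for a sample x is the mean
    prediction over the background rows with the features in S replaced by
    x's values (features outside S keep the background values).  All 2^d
    coalitions are enumerated exactly, so the efficiency property
    baseline + Σ attributions = model_fn(x) holds to numerical precision.
    Limited to d ≤ 12 features.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    n, d = X.shape
    if background.shape[1] != d:
        raise ValueError("background feature count must match X")
    if d > MAX_EXACT_FEATURES:
        raise ValueError(f"exact enumeration supports at most {MAX_EXACT_FEATURES} features")

    subsets = [frozenset(c) for s in range(d + 1) for c in combinations(range(d), s)]
    subset_pos = {s: i for i, s in enumerate(subsets)}
    weights = {
        s: factorial(s) * factorial(d - s - 1) / factorial(d) for s in range(d)
    }

    n_bg = background.shape[0]
    values = np.zeros((n, d))
    baseline = float(np.mean(model_fn(background)))
    for i in range(n):
        # one batched prediction over every coalition-completed background row
        stacked = np.tile(background, (len(subsets), 1))
        for j, s in enumerate(subsets):
            if s:
                stacked[j * n_bg:(j + 1) * n_bg, list(s)] = X[i, list(s)]
        preds = np.asarray(model_fn(stacked), dtype=float).reshape(len(subsets), n_bg)
        v = preds.mean(axis=1)
        for feat in range(d):
            phi = 0.0
            for s in subsets:
                if feat in s:
                    continue
                phi += weights[len(s)] * (v[subset_pos[s | {feat}]] - v[subset_pos[s]])
            values[i, feat] = phi
    return AttributionMatrix(
        values=values,
        baseline=baseline,
        feature_importance=np.abs(values).mean(axis=0),
        feature_names=list(feature_names) if feature_names is not None else [],
    )
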