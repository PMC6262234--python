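"""Gradient-boosted toxicity classifier: training, cross-validation,
leave-one-out scoring and SHAP interrogation.

A LightGBM binary-logistic ensemble is fit on the feature matrix; missing
covariates (NaN) are routed natively by the trees, so no imputation happens
anywhere.  Scores are raw margins (log-odds scale).  Evaluation pools
out-of-fold scores from a stratified k-fold into a single ROC; the optimal
trade-off point maximizes sensitivity + specificity (Youden index).  SHAP
attributions come from the ensemble's exact TreeSHAP path (additive:
per-drug contributions plus the expected value reconstruct the raw score).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

DEFAULT_HYPER_PARAMS: dict = {
    "objective": "binary",
    "n_estimators": 500,
    "max_depth": 6,
    "num_leaves": 63,
    "learning_rate": 0.05,
    "n_jobs": 1,
    "verbosity": -1,
    "deterministic": True,
    "force_row_wise": True,
}


def _encode_labels(labels) -> np.ndarray:
    y = np.asarray(pd.Series(labels).map(
        lambda v: {"toxic": 1, "safe": 0}.get(v, v)
    ), dtype=float)
    if np.isnan(y).any():
        raise ValueError("labels contain unlabeled entries")
    y = y.astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary (toxic/safe or 1/0)")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    return y


@dataclass(frozen=True)
class DataSplit:
    """Stratified train/hold-out index split (indices into the input order)."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def __post_init__(self):
        overlap = set(self.train_idx) & set(self.test_idx)
        if overlap:
            raise ValueError("train and test indices overlap")


def stratified_split(labels, test_fraction: float = 0.2, seed: int = 0) -> DataSplit:
    """80:20 by default, preserving the class ratio; deterministic per seed."""
    y = _encode_labels(labels)
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    return DataSplit(
        train_idx=np.sort(train_idx), test_idx=np.sort(test_idx), seed=seed
    )


@dataclass
class ToxicityModel:
    """Fitted ensemble plus the feature schema and training metadata."""

    booster: lgb.Booster
    feature_names: tuple[str, ...]
    params: dict
    seed: int
    n_training_rows: int

    def _check_schema(self, X: pd.DataFrame) -> pd.DataFrame:
        if tuple(X.columns) != self.feature_names:
            raise ValueError(
                "feature schema mismatch: model was trained on "
                f"{list(self.feature_names)}, got {list(X.columns)}"
            )
        return X

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        """Raw margin scores (log-odds scale)."""
        self._check_schema(X)
        return np.asarray(self.booster.predict(X.to_numpy(), raw_score=True))

    def shap_values(self, X: pd.DataFrame) -> pd.DataFrame:
        """Exact TreeSHAP attributions; last column is the expected value.

        Row sums (attributions + expected value) equal the raw scores.
        """
        self._check_schema(X)
        contrib = np.asarray(self.booster.predict(X.to_numpy(), pred_contrib=True))
        return pd.DataFrame(
            contrib,
            index=X.index,
            columns=list(self.feature_names) + ["expected_value"],
        )

    def feature_importances(self) -> pd.Series:
        return pd.Series(
            self.booster.feature_importance(importance_type="gain"),
            index=list(self.feature_names),
            name="gain",
        )

    def save(self, path: str | Path) -> None:
        payload = {
            "feature_names": list(self.feature_names),
            "params": self.params,
            "seed": self.seed,
            "n_training_rows": self.n_training_rows,
            "booster": self.booster.model_to_string(),
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "ToxicityModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            booster=lgb.Booster(model_str=payload["booster"]),
            feature_names=tuple(payload["feature_names"]),
            params=payload["params"],
            seed=payload["seed"],
            n_training_rows=payload["n_training_rows"],
        )


def _resolve_params(hyper_params: dict | None, seed: int) -> tuple[dict, int]:
    params = dict(DEFAULT_HYPER_PARAMS)
    if hyper_params:
        params.update(hyper_params)
    n_estimators = int(params.pop("n_estimators", 500))
    params["seed"] = seed
    return params, n_estimators


def train(
    X: pd.DataFrame,
    labels,
    hyper_params: dict | None = None,
    seed: int = 0,
) -> ToxicityModel:
    """Fit the boosted ensemble; NaN cells are handled natively."""
    y = _encode_labels(labels)
    if len(y) != len(X):
        raise ValueError("features and labels differ in length")
    params, n_estimators = _resolve_params(hyper_params, seed)
    dataset = lgb.Dataset(
        X.to_numpy(), label=y, feature_name=list(X.columns), params=params
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=UserWarning)
        booster = lgb.train(params, dataset, num_boost_round=n_estimators)
    return ToxicityModel(
        booster=booster,
        feature_names=tuple(X.columns),
        params={**params, "n_estimators": n_estimators},
        seed=seed,
        n_training_rows=len(X),
    )


@dataclass
class EvaluationReport:
    """Pooled-ROC evaluation: curve, AUC and the optimal trade-off point."""

    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    sensitivity: float  # % at the Youden-optimal point
    specificity: float  # %
    scores: pd.Series  # per-drug raw scores
    labels: np.ndarray
    folds: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "n": int(len(self.labels)),
        }


def evaluate_scores(scores, labels, folds=None) -> EvaluationReport:
    """ROC/AUC of raw scores against binary labels, ties counted 1/2."""
    y = _encode_labels(labels)
    s = pd.Series(scores)
    auc = float(roc_auc_score(y, s.to_numpy()))
    fpr, tpr, thr = roc_curve(y, s.to_numpy())
    youden = tpr - fpr
    best = int(np.argmax(youden))
    return EvaluationReport(
        auc=auc,
        fpr=fpr,
        tpr=tpr,
        thresholds=thr,
        sensitivity=float(100 * tpr[best]),
        specificity=float(100 * (1 - fpr[best])),
        scores=s,
        labels=y,
        folds=None if folds is None else np.asarray(folds),
    )


def cross_validate(
    X: pd.DataFrame,
    labels,
    k: int = 5,
    seed: int = 0,
    hyper_params: dict | None = None,
) -> EvaluationReport:
    """Stratified k-fold; out-of-fold raw scores pooled into one ROC."""
    y = _encode_labels(labels)
    class_min = int(np.bincount(y).min())
    if k < 2 or k > class_min:
        raise ValueError(
            f"k must be between 2 and the minority class count ({class_min})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    scores = np.empty(len(y))
    folds = np.empty(len(y), dtype=int)
    for f, (tr, te) in enumerate(skf.split(X, y)):
        model = train(X.iloc[tr], y[tr], hyper_params=hyper_params, seed=seed)
        scores[te] = model.predict(X.iloc[te])
        folds[te] = f
    report = evaluate_scores(pd.Series(scores, index=X.index), y)
    report.folds = folds
    return report


def loo_scores(
    X: pd.DataFrame,
    labels,
    seed: int = 0,
    hyper_params: dict | None = None,
) -> pd.Series:
    """Leave-one-out raw scores: each drug scored by a model trained
    without it."""
    y = _encode_labels(labels)
    if len(y) < 3:
        raise ValueError("leave-one-out needs at least 3 drugs")
    out = np.empty(len(y))
    for i in range(len(y)):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        model = train(X.iloc[mask], y[mask], hyper_params=hyper_params, seed=seed)
        out[i] = float(model.predict(X.iloc[[i]])[0])
    return pd.Series(out, index=X.index, name="loo_score")


@dataclass
class ShapReport:
    """Per-drug attributions plus group contrast and allocation tables."""

    attributions: pd.DataFrame  # rows = drugs, last column expected_value
    comparison: pd.DataFrame  # per-feature rank test between the groups
    allocation: pd.DataFrame  # % of positive attribution per feature per group


def shap_report(
    model: ToxicityModel,
    X: pd.DataFrame,
    group_a: Sequence[int],
    group_b: Sequence[int],
    group_names: tuple[str, str] = ("group_a", "group_b"),
) -> ShapReport:
    """Contrast per-feature SHAP distributions between two disjoint groups.

    The comparison uses the unpaired two-sided rank-sum (Mann-Whitney) test
    per feature.  The allocation table gives, per group, each feature's
    share of the total positive attribution mass, in percent.
    """
    ga, gb = list(group_a), list(group_b)
    if not ga or not gb:
        raise ValueError("both groups must be nonempty")
    if set(ga) & set(gb):
        raise ValueError("groups must be disjoint")
    n = len(X)
    for i in ga + gb:
        if not (0 <= i < n):
            raise IndexError(f"row index {i} out of range")
    attr = model.shap_values(X)
    feats = list(model.feature_names)
    rows = []
    for f in feats:
        a, b = attr[f].to_numpy()[ga], attr[f].to_numpy()[gb]
        if np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            p = 1.0
        else:
            p = float(mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(
            {
                "feature": f,
                f"mean_shap_{group_names[0]}": float(a.mean()),
                f"mean_shap_{group_names[1]}": float(b.mean()),
                "p_value": p,
            }
        )
    comparison = pd.DataFrame(rows)

    def positive_allocation(indices):
        pos = attr.iloc[indices][feats].clip(lower=0)
        total = float(pos.to_numpy().sum())
        if total == 0:
            return pd.Series(0.0, index=feats)
        return 100.0 * pos.sum(axis=0) / total

    allocation = pd.DataFrame(
        {
            group_names[0]: positive_allocation(ga),
            group_names[1]: positive_allocation(gb),
        }
    )
    allocation.index.name = "feature"
    return ShapReport(attributions=attr, comparison=comparison, allocation=allocation)
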