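"""RBF-kernel SVM training, prediction and cross-validated evaluation.

The classifier is a support vector machine with a radial basis function
kernel, cost and gamma tuned by exhaustive grid search over the standard
libsvm-guide lattice (cost 2^-5..2^15, gamma 2^-15..2^3, steps of 2^2).
Features are standardized with training-fold mean/SD before fitting — the
fused feature space mixes {0,1} indicators with small frequency values, and
an RBF kernel is scale-sensitive.  A sample is called a 6mA site iff its
predicted probability exceeds 0.5 (strictly; a tie at exactly 0.5 is a
negative call).

Evaluation is stratified n-fold cross-validation reporting sensitivity,
specificity, accuracy, Matthews correlation and ROC AUC per fold and on
average, optionally averaged again over repeated fold assignments.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureMatrix

__all__ = [
    "DEFAULT_GRID",
    "ConfusionCounts",
    "EvaluationReport",
    "ModelBundle",
    "grid_search_train",
    "predict",
    "compute_metrics",
    "roc_auc",
    "cross_validate",
]

# We deliberately use libsvm-style Platt probabilities (the 50% call rule);
# sklearn 1.9 deprecates the flag in favor of an equivalent wrapper.
warnings.filterwarnings(
    "ignore", message="The `probability` parameter", category=FutureWarning
)

# libsvm practical-guide lattice
DEFAULT_GRID: dict[str, list[float]] = {
    "cost": [2.0**e for e in range(-5, 16, 2)],
    "gamma": [2.0**e for e in range(-15, 4, 2)],
}


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts of one evaluation."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_calls(cls, y_true: np.ndarray, y_call: np.ndarray) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_call = np.asarray(y_call, dtype=int)
        return cls(
            TP=int(((y_true == 1) & (y_call == 1)).sum()),
            TN=int(((y_true == 0) & (y_call == 0)).sum()),
            FP=int(((y_true == 0) & (y_call == 1)).sum()),
            FN=int(((y_true == 1) & (y_call == 0)).sum()),
        )


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Sn, Sp, ACC and MCC from confusion counts.

    Zero-denominator conventions: an undefined Sn or Sp is reported as 0.0;
    MCC with any zero factor under the root is 0.0.
    """
    sn = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    sp = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else 0.0
    acc = (c.TP + c.TN) / c.total if c.total else 0.0
    denom = (c.TN + c.FN) * (c.TN + c.FP) * (c.TP + c.FN) * (c.TP + c.FP)
    mcc = (c.TP * c.TN - c.FP * c.FN) / np.sqrt(denom) if denom else 0.0
    return {"Sn": float(sn), "Sp": float(sp), "ACC": float(acc), "MCC": float(mcc)}


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """AUC and ROC points (FPR, TPR) by threshold sweep.

    The AUC equals the probability that a random positive outscores a random
    negative, ties counting one half.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = _sk_roc_curve(labels, scores)
    return float(_sk_auc(fpr, tpr)), np.column_stack([fpr, tpr])


def _make_pipeline(kernel: str, cost: float, gamma, seed: int, probability: bool = True) -> Pipeline:
    return make_pipeline(
        StandardScaler(),
        SVC(kernel=kernel, C=cost, gamma=gamma, probability=probability, random_state=seed),
    )


@dataclass
class ModelBundle:
    """A trained, reloadable classifier with its preprocessing and metadata.

    ``pipeline`` is the fitted scaler+SVC; ``selected_indices`` are the
    column indices of the full (fused) feature space the model consumes.
    """

    pipeline: Pipeline
    kernel: str
    cost: float
    gamma: float | str
    selected_indices: np.ndarray
    feature_names: list[str]
    seed: int
    grid_searched: bool = False
    metadata: dict = field(default_factory=dict)

    def save(self, prefix: str | Path) -> None:
        """Write ``<prefix>.json`` (metadata) and ``<prefix>.joblib`` (fitted model)."""
        prefix = Path(prefix)
        meta = {
            "kernel": self.kernel,
            "cost": self.cost,
            "gamma": self.gamma,
            "selected_indices": np.asarray(self.selected_indices).tolist(),
            "feature_names": self.feature_names,
            "seed": self.seed,
            "grid_searched": self.grid_searched,
            "metadata": self.metadata,
        }
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))
        joblib.dump(self.pipeline, prefix.with_suffix(".joblib"))

    @classmethod
    def load(cls, prefix: str | Path) -> "ModelBundle":
        prefix = Path(prefix)
        meta = json.loads(prefix.with_suffix(".json").read_text())
        return cls(
            pipeline=joblib.load(prefix.with_suffix(".joblib")),
            kernel=meta["kernel"],
            cost=meta["cost"],
            gamma=meta["gamma"],
            selected_indices=np.array(meta["selected_indices"], dtype=int),
            feature_names=meta["feature_names"],
            seed=meta["seed"],
            grid_searched=meta["grid_searched"],
            metadata=meta["metadata"],
        )


def grid_search_train(
    M: FeatureMatrix,
    grid: Optional[dict[str, Sequence[float]]] = None,
    folds: int = 5,
    seed: int = 0,
    kernel: str = "rbf",
    selected_indices: Optional[Sequence[int]] = None,
) -> ModelBundle:
    """Exhaustive (cost, gamma) search by inner stratified CV accuracy,
    then refit on all data with the best pair.

    Ties are broken toward the smallest cost, then the smallest gamma.
    Deterministic given the seed.
    """
    if M.labels is None:
        raise ValueError("labeled matrix required")
    grid = dict(DEFAULT_GRID if grid is None else grid)
    X = M.values if selected_indices is None else M.values[:, list(selected_indices)]
    y = M.labels
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise ValueError(f"need >= {folds} samples per class for {folds}-fold inner CV")
    # ascending param order + argmin-of-rank => smallest cost then gamma on ties
    gammas = sorted(v for v in grid["gamma"] if not isinstance(v, str))
    gammas += [v for v in grid["gamma"] if isinstance(v, str)]  # e.g. "scale"
    param_grid = {"svc__C": sorted(grid["cost"]), "svc__gamma": gammas}
    pipe = _make_pipeline(kernel, 1.0, "scale", seed, probability=False)
    search = GridSearchCV(
        pipe,
        param_grid,
        scoring="accuracy",
        cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed),
        n_jobs=1,
    )
    search.fit(X, y)
    cost = float(search.best_params_["svc__C"])
    gamma = search.best_params_["svc__gamma"]
    if not isinstance(gamma, str):
        gamma = float(gamma)
    final = _make_pipeline(kernel, cost, gamma, seed, probability=True)
    final.fit(X, y)
    idx = np.arange(M.n_features) if selected_indices is None else np.asarray(list(selected_indices), dtype=int)
    return ModelBundle(
        pipeline=final,
        kernel=kernel,
        cost=cost,
        gamma=gamma,
        selected_indices=idx,
        feature_names=[M.feature_names[i] for i in idx],
        seed=seed,
        grid_searched=True,
        metadata={"cv_folds": folds, "best_inner_accuracy": float(search.best_score_)},
    )


def predict(model: ModelBundle, M: FeatureMatrix) -> pd.DataFrame:
    """Per-sample 6mA probability and binary call (probability > 0.5)."""
    n_expected = len(model.selected_indices)
    if M.n_features == n_expected and M.feature_names == model.feature_names:
        X = M.values
    elif M.n_features > n_expected:
        X = M.values[:, model.selected_indices]
    else:
        raise ValueError(
            f"feature mismatch: model expects {n_expected} selected of a wider "
            f"matrix, got {M.n_features} columns"
        )
    proba = model.pipeline.predict_proba(X)[:, 1]
    return pd.DataFrame({"id": M.ids, "probability": proba, "call": (proba > 0.5).astype(int)})


@dataclass
class EvaluationReport:
    """Per-fold and mean metrics of a (repeated) stratified n-fold CV."""

    fold_metrics: pd.DataFrame  # columns: repeat, fold, Sn, Sp, ACC, MCC, AUC
    mean_metrics: dict[str, float]
    confusion: ConfusionCounts  # pooled over folds of the first repeat
    roc_points: np.ndarray  # pooled (FPR, TPR) of the first repeat
    fold_rocs: list[np.ndarray]
    seed: int
    n_folds: int
    repeats: int

    def summary(self) -> str:
        m = self.mean_metrics
        lines = [
            f"{self.n_folds}-fold cross-validation"
            + (f" x {self.repeats} repeats" if self.repeats > 1 else "")
            + f" (seed {self.seed})",
            "-" * 46,
            f"  Sn  (sensitivity)          {m['Sn']:.4f}",
            f"  Sp  (specificity)          {m['Sp']:.4f}",
            f"  ACC (accuracy)             {m['ACC']:.4f}",
            f"  MCC (Matthews corr.)       {m['MCC']:.4f}",
            f"  AUC (area under ROC)       {m['AUC']:.4f}",
            "-" * 46,
            f"  pooled confusion: TP={self.confusion.TP} TN={self.confusion.TN} "
            f"FP={self.confusion.FP} FN={self.confusion.FN}",
        ]
        return "\n".join(lines)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": self.mean_metrics,
            "folds": self.fold_metrics.to_dict(orient="records"),
            "confusion": {"TP": self.confusion.TP, "TN": self.confusion.TN,
                          "FP": self.confusion.FP, "FN": self.confusion.FN},
            "seed": self.seed,
            "n_folds": self.n_folds,
            "repeats": self.repeats,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    def roc_to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.roc_points, columns=["FPR", "TPR"]).to_csv(path, sep="\t", index=False)


def cross_validate(
    M: FeatureMatrix,
    n: int = 10,
    seed: int = 0,
    repeats: int = 1,
    kernel: str = "rbf",
    cost: float = 1.0,
    gamma: float | str = "scale",
    selected_indices: Optional[Sequence[int]] = None,
) -> EvaluationReport:
    """Stratified n-fold CV of a fixed-hyperparameter SVM.

    Each fold trains scaler+SVC on n-1 subsets and scores the held-out one;
    metrics are averaged over folds, and over ``repeats`` independent fold
    assignments when ``repeats > 1``.
    """
    if M.labels is None:
        raise ValueError("labeled matrix required")
    y = M.labels
    if n < 2:
        raise ValueError("need n >= 2 folds")
    if np.bincount(y, minlength=2).min() < n:
        raise ValueError(f"n={n} folds exceed the size of the smaller class")
    X = M.values if selected_indices is None else M.values[:, list(selected_indices)]

    rows = []
    fold_rocs: list[np.ndarray] = []
    pooled_scores = np.empty(len(y))
    pooled_calls = np.empty(len(y), dtype=int)
    for rep in range(repeats):
        rep_seed = seed + rep
        cv = StratifiedKFold(n_splits=n, shuffle=True, random_state=rep_seed)
        for fold, (tr, te) in enumerate(cv.split(X, y)):
            clf = _make_pipeline(kernel, cost, gamma, rep_seed)
            clf.fit(X[tr], y[tr])
            proba = clf.predict_proba(X[te])[:, 1]
            calls = (proba > 0.5).astype(int)
            counts = ConfusionCounts.from_calls(y[te], calls)
            metrics = compute_metrics(counts)
            metrics["AUC"], roc_pts = roc_auc(proba, y[te])
            rows.append({"repeat": rep, "fold": fold, **metrics})
            if rep == 0:
                fold_rocs.append(roc_pts)
                pooled_scores[te] = proba
                pooled_calls[te] = calls
    fold_df = pd.DataFrame(rows)
    mean = {k: float(fold_df[k].mean()) for k in ("Sn", "Sp", "ACC", "MCC", "AUC")}
    pooled_auc, pooled_roc = roc_auc(pooled_scores, y)
    return EvaluationReport(
        fold_metrics=fold_df,
        mean_metrics=mean,
        confusion=ConfusionCounts.from_calls(y, pooled_calls),
        roc_points=pooled_roc,
        fold_rocs=fold_rocs,
        seed=seed,
        n_folds=n,
        repeats=repeats,
    )
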