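"""Multimodal prognosis classification and its evaluation protocol.

The image-derived pathological risk score is appended to the 18 clinical
variables and a gradient-boosted tree classifier (XGBoost or LightGBM
backend) predicts the binary one-year cardiovascular-event outcome from the
19 features. The evaluation protocol mirrors the study design:

* patient-level 7:3 train/test splits (all data of a patient on one side),
  class-stratified, train size = round-half-up(0.7 N);
* 5-fold stratified cross-validated grid search on the training set,
  selecting the configuration with the lowest mean validation log loss;
* an operating threshold chosen by the Youden index (J = sensitivity +
  specificity - 1) on out-of-fold training predictions;
* ROC-AUC, accuracy, sensitivity, specificity and F1 on the held-out test
  set, repeated over n independent splits and aggregated as mean with a
  normal-approximation 95% confidence interval.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import log_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from . import schema

__all__ = [
    "assemble_features", "SplitPlan", "split_patients",
    "DEFAULT_GRID", "make_model", "select_config", "fit_classifier",
    "oof_predictions", "youden_threshold", "youden_index", "binary_metrics",
    "evaluate", "EvaluationReport", "repeated_evaluation", "feature_importances",
]


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

def assemble_features(clinical: pd.DataFrame, risk: pd.Series | dict) -> pd.DataFrame:
    """Join clinical variables with per-patient risk scores; mean-impute.

    Missing cells (numeric and 0/1 indicator columns alike) are filled with
    the mean of the observed values in their column. Raises when the patient
    sets of the two inputs differ, or when a column has no observed value.
    """
    risk = pd.Series(risk, dtype=float) if isinstance(risk, dict) else risk.astype(float)
    clin_ids = set(clinical[schema.ID_COLUMN])
    risk_ids = set(risk.index)
    if clin_ids != risk_ids:
        missing = sorted(clin_ids ^ risk_ids)
        raise ValueError(f"clinical rows and risk scores disagree on patients: {missing}")
    df = clinical.set_index(schema.ID_COLUMN).copy()
    for col in schema.CLINICAL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"clinical table lacks column {col!r}")
        observed = df[col].dropna()
        if observed.empty:
            raise ValueError(f"column {col!r} has no observed values to impute from")
        df[col] = df[col].fillna(float(observed.mean()))
    df[schema.RISK_COLUMN] = risk
    cols = schema.CLINICAL_COLUMNS + [schema.RISK_COLUMN, schema.LABEL_COLUMN]
    return df[cols].reset_index()


# ---------------------------------------------------------------------------
# patient-level splitting
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SplitPlan:
    train_ids: list[str]
    test_ids: list[str]
    ratio: float
    seed: int


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_patients(table: pd.DataFrame, ratio: float = 0.7, seed: int = 0) -> SplitPlan:
    """Class-stratified patient-level split; train size = round(ratio * N)."""
    labels = table.set_index(schema.ID_COLUMN)[schema.LABEL_COLUMN]
    classes = sorted(labels.unique())
    if len(classes) < 2 or any((labels == c).sum() < 2 for c in classes):
        raise ValueError("need at least 2 patients in each class")
    rng = np.random.default_rng(seed)
    n_total = len(labels)
    target = _round_half_up(ratio * n_total)
    per_class = {c: _round_half_up(ratio * (labels == c).sum()) for c in classes}
    # reconcile per-class rounding with the overall target on the largest class
    largest = max(classes, key=lambda c: (labels == c).sum())
    per_class[largest] += target - sum(per_class.values())
    train_ids: list[str] = []
    test_ids: list[str] = []
    for c in classes:
        ids = labels.index[labels == c].to_numpy()
        n_train = int(np.clip(per_class[c], 1, len(ids) - 1))
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[perm[:n_train]])
        test_ids.extend(ids[perm[n_train:]])
    for side in (train_ids, test_ids):
        present = set(labels.loc[side])
        if present != set(classes):
            raise ValueError("a class is absent from one side of the split")
    return SplitPlan(train_ids=sorted(train_ids), test_ids=sorted(test_ids),
                     ratio=ratio, seed=seed)


# ---------------------------------------------------------------------------
# model backends and grid search
# ---------------------------------------------------------------------------

DEFAULT_GRID: dict[str, list] = {
    "max_depth": [2, 4],
    "learning_rate": [0.1, 0.3],
    "n_estimators": [50],
}


def make_model(backend: str, cfg: dict, seed: int = 0):
    """Instantiate a gradient-boosting classifier of the requested family."""
    if backend == "xgboost_like":
        from xgboost import XGBClassifier

        return XGBClassifier(random_state=seed, n_jobs=1, verbosity=0,
                             tree_method="hist", eval_metric="logloss", **cfg)
    if backend == "lightgbm_like":
        from lightgbm import LGBMClassifier

        return LGBMClassifier(random_state=seed, n_jobs=1, verbose=-1,
                              min_child_samples=5, **cfg)
    raise ValueError(f"unknown backend {backend!r}")


def _grid_points(grid: dict[str, list]) -> list[dict]:
    keys = list(grid)
    return [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]


def select_config(configs: Sequence[dict], loss_fn: Callable[[dict], float]):
    """Argmin of a loss over configurations (first wins on ties)."""
    if not configs:
        raise ValueError("empty hyperparameter grid")
    losses = [float(loss_fn(cfg)) for cfg in configs]
    best = int(np.argmin(losses))
    return configs[best], losses


def _xy(table: pd.DataFrame, feature_columns: Sequence[str]):
    x = table[list(feature_columns)].to_numpy(dtype=float)
    y = table[schema.LABEL_COLUMN].to_numpy(dtype=int)
    return x, y


def cv_log_loss(table: pd.DataFrame, backend: str, cfg: dict,
                feature_columns: Sequence[str], folds: int = 5, seed: int = 0) -> float:
    """Mean validation log loss of one configuration over stratified folds."""
    x, y = _xy(table, feature_columns)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    losses = []
    for tr, va in skf.split(x, y):
        model = make_model(backend, cfg, seed=seed)
        model.fit(x[tr], y[tr])
        probs = model.predict_proba(x[va])[:, 1]
        losses.append(log_loss(y[va], probs, labels=[0, 1]))
    return float(np.mean(losses))


def fit_classifier(train: pd.DataFrame, backend: str = "xgboost_like",
                   grid: dict[str, list] | None = None, folds: int = 5,
                   seed: int = 0, feature_columns: Sequence[str] | None = None):
    """Grid search by cross-validated log loss, then refit on all of train.

    Returns (fitted model, selected config, per-config CV losses).
    """
    grid = grid or DEFAULT_GRID
    feature_columns = list(feature_columns or _default_features(train))
    y = train[schema.LABEL_COLUMN]
    if y.nunique() < 2:
        raise ValueError("training data contains a single class")
    configs = _grid_points(grid)
    best_cfg, losses = select_config(
        configs, lambda cfg: cv_log_loss(train, backend, cfg, feature_columns,
                                         folds=folds, seed=seed))
    model = make_model(backend, best_cfg, seed=seed)
    x, yv = _xy(train, feature_columns)
    model.fit(x, yv)
    return model, best_cfg, dict(zip(map(str, configs), losses))


def oof_predictions(train: pd.DataFrame, backend: str, cfg: dict,
                    feature_columns: Sequence[str], folds: int = 5,
                    seed: int = 0) -> np.ndarray:
    """Out-of-fold predicted probabilities on the training set."""
    x, y = _xy(train, feature_columns)
    probs = np.empty(len(y), dtype=float)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for tr, va in skf.split(x, y):
        model = make_model(backend, cfg, seed=seed)
        model.fit(x[tr], y[tr])
        probs[va] = model.predict_proba(x[va])[:, 1]
    return probs


def _default_features(table: pd.DataFrame) -> list[str]:
    cols = list(schema.CLINICAL_COLUMNS)
    if schema.RISK_COLUMN in table.columns:
        cols.append(schema.RISK_COLUMN)
    return cols


# ---------------------------------------------------------------------------
# thresholding and metrics
# ---------------------------------------------------------------------------

def youden_index(scores: np.ndarray, labels: np.ndarray, threshold: float) -> float:
    """J = sensitivity + specificity - 1 at ``threshold`` (positive: >=)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    pos, neg = labels == 1, labels == 0
    sens = pred[pos].mean() if pos.any() else 0.0
    spec = (~pred[neg]).mean() if neg.any() else 0.0
    return float(sens + spec - 1.0)


def youden_threshold(scores: Sequence[float], labels: Sequence[int]):
    """Threshold maximizing the Youden index.

    Candidates are the midpoints between consecutive distinct sorted scores
    plus -inf/+inf sentinels; ties are broken toward the higher threshold
    (higher specificity). Returns (threshold, J).
    """
    scores = np.asarray(list(scores), dtype=float)
    labels = np.asarray(list(labels), dtype=int)
    if len(set(labels.tolist()) & {0, 1}) < 2:
        raise ValueError("both outcome classes are required")
    uniq = np.unique(scores)
    cands = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]])
    js = np.array([youden_index(scores, labels, t) for t in cands])
    best_j = js.max()
    best_t = cands[js == best_j].max()
    return float(best_t), float(best_j)


def binary_metrics(labels: np.ndarray, probs: np.ndarray, threshold: float) -> dict:
    """Thresholded confusion-matrix metrics plus rank-based ROC-AUC.

    AUC is None (flagged) when the test set contains a single class.
    """
    labels = np.asarray(labels, dtype=int)
    probs = np.asarray(probs, dtype=float)
    pred = (probs >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / len(labels)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0
    auc = float(roc_auc_score(labels, probs)) if len(np.unique(labels)) == 2 else None
    return {"roc_auc": auc, "accuracy": acc, "sensitivity": sens,
            "specificity": spec, "f1": f1, "threshold": float(threshold)}


def evaluate(fitted, test: pd.DataFrame, threshold: float,
             feature_columns: Sequence[str] | None = None) -> dict:
    """Test-set metrics of a fitted model at a fixed operating threshold."""
    if test.empty:
        raise ValueError("empty test set")
    feature_columns = list(feature_columns or _default_features(test))
    x, y = _xy(test, feature_columns)
    probs = fitted.predict_proba(x)[:, 1]
    return binary_metrics(y, probs, threshold)


# ---------------------------------------------------------------------------
# repeated evaluation protocol
# ---------------------------------------------------------------------------

_METRICS = ("roc_auc", "accuracy", "sensitivity", "specificity", "f1")


@dataclasses.dataclass
class EvaluationReport:
    per_rep: pd.DataFrame           # one row per repetition
    aggregates: dict                # metric -> {mean, ci_lo, ci_hi}
    n_repetitions: int
    substitutions: list[dict]       # seeds redrawn due to failed preconditions

    def to_dict(self) -> dict:
        return {
            "n_repetitions": self.n_repetitions,
            "aggregates": self.aggregates,
            "per_repetition": self.per_rep.to_dict(orient="records"),
            "substitutions": self.substitutions,
        }


def _aggregate(values: np.ndarray) -> dict:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    half = float(1.96 * sd / np.sqrt(len(values)))
    return {"mean": mean, "ci_lo": mean - half, "ci_hi": mean + half}


def repeated_evaluation(table: pd.DataFrame, n_reps: int = 100,
                        backend: str = "xgboost_like",
                        grid: dict[str, list] | None = None, folds: int = 5,
                        ratio: float = 0.7, base_seed: int = 0,
                        feature_columns: Sequence[str] | None = None,
                        ) -> EvaluationReport:
    """Run the full repeated-split protocol; see module docstring.

    Repetition i uses seed base_seed + i for the split, fold assignment and
    model fits, so the whole report is reproducible from the base seed. A
    repetition whose split violates class-presence preconditions is redrawn
    with a recorded substitute seed. Train/test patient disjointness is
    asserted in every repetition.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    feature_columns = list(feature_columns or _default_features(table))
    rows = []
    substitutions: list[dict] = []
    for i in range(n_reps):
        seed = base_seed + i
        plan = None
        for attempt in range(25):
            try:
                plan = split_patients(table, ratio=ratio, seed=seed)
                break
            except ValueError:
                substitutions.append({"repetition": i, "failed_seed": seed})
                seed = base_seed + n_reps + 1009 * (i + 1) + attempt
        if plan is None:
            raise RuntimeError(f"could not draw a valid split for repetition {i}")
        assert not set(plan.train_ids) & set(plan.test_ids), "train/test leakage"
        assert set(plan.train_ids) | set(plan.test_ids) == set(table[schema.ID_COLUMN])
        train = table[table[schema.ID_COLUMN].isin(plan.train_ids)]
        test = table[table[schema.ID_COLUMN].isin(plan.test_ids)]
        model, best_cfg, _ = fit_classifier(train, backend=backend, grid=grid,
                                            folds=folds, seed=seed,
                                            feature_columns=feature_columns)
        oof = oof_predictions(train, backend, best_cfg, feature_columns,
                              folds=folds, seed=seed)
        thr, _j = youden_threshold(oof, train[schema.LABEL_COLUMN].to_numpy())
        metrics = evaluate(model, test, thr, feature_columns=feature_columns)
        metrics["repetition"] = i
        metrics["seed"] = seed
        rows.append(metrics)
    per_rep = pd.DataFrame(rows)
    aggregates = {m: _aggregate(per_rep[m].dropna().to_numpy()) for m in _METRICS}
    return EvaluationReport(per_rep=per_rep, aggregates=aggregates,
                            n_repetitions=n_reps, substitutions=substitutions)


def feature_importances(fitted, feature_columns: Sequence[str]) -> pd.Series:
    """Total-gain feature importances of a fitted backend (thin pass-through)."""
    if hasattr(fitted, "get_booster"):  # xgboost
        raw = fitted.get_booster().get_score(importance_type="total_gain")
        vals = [raw.get(f"f{i}", 0.0) for i in range(len(feature_columns))]
    else:  # lightgbm
        vals = fitted.booster_.feature_importance(importance_type="gain")
    return pd.Series(vals, index=list(feature_columns)).sort_values(ascending=False)
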