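"""Task-model training, variable selection, calibration and clinical baselines."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import average_precision_score
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix
from .labels import LBL_UNDEFINED
from .treeshap import TreeEnsemble

DEFAULT_PARAMS = dict(
    learning_rate=0.05,
    max_leaf_nodes=31,
    min_samples_leaf=20,
    l2_regularization=1.0,
)
MAX_ROUNDS = 300
EARLY_STOP_PATIENCE = 50

#: 20-point hyperparameter grid used for the extubation-failure task.
EF_PARAM_GRID = [
    dict(DEFAULT_PARAMS, learning_rate=lr, max_leaf_nodes=leaves)
    for lr in (0.02, 0.05, 0.1, 0.2)
    for leaves in (7, 15, 31, 63, 127)
]


@dataclass
class SplitPlan:
    test_ids: list
    replicates: list[tuple[list, list]]  # (train_ids, val_ids)

    def __post_init__(self):
        test = set(self.test_ids)
        for tr, va in self.replicates:
            if test & set(tr) or test & set(va):
                raise ValueError("test ids leak into development splits")
            if set(tr) & set(va):
                raise ValueError("train/validation overlap")


def make_splits(
    stay_ids: Sequence,
    n_replicates: int = 5,
    seed: int = 0,
    test_fraction: float = 0.2,
    val_fraction: float = 0.2,
) -> SplitPlan:
    """One fixed held-out test set plus ``n_replicates`` random 80:20
    train/validation partitions of the development stays (split by patient)."""
    ids = list(stay_ids)
    if len(ids) < 10:
        raise ValueError("need at least 10 stays to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_test = max(1, int(round(test_fraction * len(ids))))
    test = [ids[i] for i in perm[:n_test]]
    dev = [ids[i] for i in perm[n_test:]]
    reps = []
    for r in range(n_replicates):
        sub = np.random.default_rng(seed + 1000 + r).permutation(len(dev))
        n_val = max(1, int(round(val_fraction * len(dev))))
        val = [dev[i] for i in sub[:n_val]]
        train = [dev[i] for i in sub[n_val:]]
        reps.append((train, val))
    return SplitPlan(test_ids=test, replicates=reps)


@dataclass
class TaskModel:
    task: str
    model: HistGradientBoostingClassifier
    feature_names: list[str]
    best_iteration: int
    val_auprc: float
    seed: int
    params: dict = field(default_factory=dict)

    def predict_scores(self, frame: pd.DataFrame) -> np.ndarray:
        X = frame[self.feature_names].to_numpy(dtype=float)
        return self.model.predict_proba(X)[:, 1]


def _defined_rows(frame: pd.DataFrame, labels: np.ndarray, stay_ids: Sequence):
    mask = (labels != LBL_UNDEFINED) & frame["stay_id"].isin(set(stay_ids)).to_numpy()
    return mask


def _staged_best_iteration(model, Xv, yv, patience=EARLY_STOP_PATIENCE):
    """Walk the staged validation AUPRC; stop after ``patience`` stages
    without improvement; return (best_iteration, best_auprc)."""
    best_iter, best_score, since = 0, -np.inf, 0
    for i, proba in enumerate(model.staged_predict_proba(Xv), start=1):
        score = average_precision_score(yv, proba[:, 1])
        if score > best_score:
            best_iter, best_score, since = i, score, 0
        else:
            since += 1
            if since >= patience:
                break
    return best_iter, best_score


def train_task_model(
    task: str,
    featmat: FeatureMatrix,
    labels: np.ndarray,
    train_ids: Sequence,
    val_ids: Sequence,
    params: Optional[dict] = None,
    seed: int = 0,
    max_rounds: int = MAX_ROUNDS,
    feature_names: Optional[list[str]] = None,
) -> TaskModel:
    """Gradient-boosted trees on rows with defined labels; boosting rounds
    chosen by validation time-point AUPRC with 50-round patience; missing
    feature values are passed through natively (no imputation or scaling)."""
    params = dict(DEFAULT_PARAMS if params is None else params)
    frame = featmat.frame
    names = feature_names if feature_names is not None else featmat.feature_columns
    tr_mask = _defined_rows(frame, labels, train_ids)
    va_mask = _defined_rows(frame, labels, val_ids)
    ytr, yva = labels[tr_mask], labels[va_mask]
    if len(np.unique(ytr)) < 2 or len(np.unique(yva)) < 2:
        raise ValueError(f"{task}: single-class labels in train or validation")
    Xtr = frame.loc[tr_mask, names].to_numpy(dtype=float)
    Xva = frame.loc[va_mask, names].to_numpy(dtype=float)
    # columns with no observed value at all carry no signal but crash the
    # histogram binner; pin them to a constant
    all_nan = np.isnan(Xtr).all(axis=0)
    if all_nan.any():
        Xtr[:, all_nan] = 0.0
        Xva[:, np.isnan(Xva).all(axis=0)] = 0.0

    probe = HistGradientBoostingClassifier(
        max_iter=max_rounds, early_stopping=False, random_state=seed, **params
    ).fit(Xtr, ytr)
    best_iter, best_score = _staged_best_iteration(probe, Xva, yva)
    model = HistGradientBoostingClassifier(
        max_iter=max(best_iter, 1), early_stopping=False, random_state=seed, **params
    ).fit(Xtr, ytr)
    return TaskModel(
        task=task,
        model=model,
        feature_names=list(names),
        best_iteration=best_iter,
        val_auprc=float(best_score),
        seed=seed,
        params=params,
    )


def grid_search_task_model(
    task, featmat, labels, train_ids, val_ids, grid=EF_PARAM_GRID, seed=0, max_rounds=MAX_ROUNDS
) -> TaskModel:
    """Small-sample variant: pick the best of a fixed hyperparameter grid by
    validation AUPRC (used for the extubation-failure task)."""
    best = None
    for params in grid:
        tm = train_task_model(
            task, featmat, labels, train_ids, val_ids, params, seed, max_rounds
        )
        if best is None or tm.val_auprc > best.val_auprc:
            best = tm
    return best


# ---------------------------------------------------------------------------
# SHAP-based importance and greedy forward selection
# ---------------------------------------------------------------------------

def shap_feature_importance(
    task_model: TaskModel,
    frame: pd.DataFrame,
    max_rows: int = 200,
    seed: int = 0,
) -> pd.Series:
    """Mean absolute SHAP value per feature on (a sample of) the given rows."""
    X = frame[task_model.feature_names].to_numpy(dtype=float)
    if len(X) > max_rows:
        idx = np.random.default_rng(seed).choice(len(X), max_rows, replace=False)
        X = X[idx]
    ens = TreeEnsemble.from_hist_gradient_boosting(task_model.model)
    phi = ens.shap_values(X)
    return pd.Series(np.abs(phi).mean(axis=0), index=task_model.feature_names)


def shap_variable_importance(
    feature_importance: pd.Series | list[pd.Series],
    featmat: FeatureMatrix,
) -> pd.Series:
    """Variable-level importance: mean over replicates of the per-feature
    mean |SHAP|, then the maximum over the features derived from each
    variable; returned descending."""
    if isinstance(feature_importance, pd.Series):
        feature_importance = [feature_importance]
    mean_imp = pd.concat(feature_importance, axis=1).mean(axis=1)
    var_of = {m["name"]: m["variable"] for m in featmat.manifest}
    grouped = mean_imp.groupby(mean_imp.index.map(var_of)).max()
    return grouped.sort_values(ascending=False)


def mean_reciprocal_rank(traces: list[list[str]]) -> pd.Series:
    """Final importance: mean of 1/rank over replicate forward traces."""
    vars_all = sorted({v for t in traces for v in t})
    out = {}
    for v in vars_all:
        rr = [1.0 / (t.index(v) + 1) for t in traces if v in t]
        out[v] = float(np.mean(rr)) if rr else 0.0
    return pd.Series(out).sort_values(ascending=False)


def greedy_forward_select(
    candidates: list[str],
    featmat: FeatureMatrix,
    labels: np.ndarray,
    splits: SplitPlan,
    params: Optional[dict] = None,
    seed: int = 0,
    max_rounds: int = 50,
    max_steps: Optional[int] = None,
) -> tuple[pd.Series, list[list[str]]]:
    """Per replicate, greedily add the variable maximising validation
    time-point AUPRC; rank variables by mean reciprocal rank across
    replicates. Returns (ranking, per-replicate traces)."""
    if not candidates:
        raise ValueError("empty candidate set")
    var_cols: dict[str, list[str]] = {}
    for m in featmat.manifest:
        var_cols.setdefault(m["variable"], []).append(m["name"])
    traces = []
    steps = max_steps if max_steps is not None else len(candidates)
    for rep, (train_ids, val_ids) in enumerate(splits.replicates):
        selected: list[str] = []
        remaining = list(candidates)
        for _ in range(steps):
            best_var, best_score = None, -np.inf
            for v in remaining:
                names = [c for u in selected + [v] for c in var_cols[u]]
                tm = train_task_model(
                    "fsel",
                    featmat,
                    labels,
                    train_ids,
                    val_ids,
                    params,
                    seed=seed + rep,
                    max_rounds=max_rounds,
                    feature_names=names,
                )
                if tm.val_auprc > best_score:
                    best_var, best_score = v, tm.val_auprc
            selected.append(best_var)
            remaining.remove(best_var)
        traces.append(selected + remaining)  # unvisited tail keeps trace length fixed
    return mean_reciprocal_rank([t[:steps] for t in traces]), traces


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass
class CalibrationReport:
    bin_edges: np.ndarray
    bin_centers: np.ndarray
    observed: np.ndarray  # event fraction per bin, NaN if empty
    counts: np.ndarray
    brier: float


def calibration_report(scores: np.ndarray, labels: np.ndarray, bin_size: float = 0.05) -> CalibrationReport:
    """Bins of fixed width between min and max score; per-bin observed event
    fraction; Brier = mean squared (score - outcome)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=float)
    lo, hi = float(np.min(s)), float(np.max(s))
    n_bins = max(1, int(np.ceil((hi - lo) / bin_size))) if hi > lo else 1
    edges = lo + bin_size * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)
    idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    sums = np.bincount(idx, weights=y, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        observed = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return CalibrationReport(
        bin_edges=edges,
        bin_centers=(edges[:-1] + edges[1:]) / 2.0,
        observed=observed,
        counts=counts,
        brier=float(np.mean((s - y) ** 2)),
    )


# ---------------------------------------------------------------------------
# clinical baselines
# ---------------------------------------------------------------------------

BASELINE_TREE_VARIABLES = ["spo2", "fio2_est", "pao2", "peep", "rr", "vent_status", "hr", "gcs"]


def sf_ratio_score(spo2: np.ndarray, fio2: np.ndarray) -> np.ndarray:
    """Threshold-alarm baseline: risk score is the negated SpO2/FIO2 ratio."""
    with np.errstate(divide="ignore", invalid="ignore"):
        return -np.asarray(spo2, float) / np.asarray(fio2, float)


def decision_tree_baseline(
    featmat: FeatureMatrix,
    labels: np.ndarray,
    train_ids: Sequence,
    variables: Sequence[str] = tuple(BASELINE_TREE_VARIABLES),
    max_depth: int = 4,
    seed: int = 0,
) -> tuple[DecisionTreeClassifier, list[str]]:
    """Shallow decision tree on current-value variables only."""
    cols = [v for v in variables if v in featmat.frame.columns]
    mask = _defined_rows(featmat.frame, labels, train_ids)
    X = featmat.frame.loc[mask, cols].to_numpy(dtype=float)
    y = labels[mask]
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed).fit(X, y)
    return tree, cols


def rext_baseline_score(violation_scores: np.ndarray) -> np.ndarray:
    """Extubation-failure baseline: the readiness violation score itself."""
    return np.asarray(violation_scores, dtype=float)
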