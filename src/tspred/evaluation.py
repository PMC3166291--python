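"""Cross-validation harness and ranking metrics.

Two validation schemes are provided.  Repeated stratified k-fold
("10x10fold": ten different 10-fold partitions, pooled per repeat) estimates
metric means and variances.  The nested "5xleaveout" scheme makes five
disjoint 80/20 splits; hyperparameters are grid-searched on each 80% (via
repeated CV) and performance is reported only on the untouched 20%, so no
reported number ever involves a sample used for tuning.  Final
hyperparameters are the component-wise medians, in log space, of the five
per-split winners.

Metrics: ts-class precision TP/(TP+FP); AUROC as the tie-aware rank
statistic (equal to the normalized Mann–Whitney U: the probability that a
random ts sample outranks a random non-ts sample); AUPR; and the
point-biserial correlation (M₁ − M₀)/s_n · √(pq) between confidence and the
0/1 truth vector, identical to the Pearson correlation with 0/1 coding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .errors import InputError, UndefinedMetricError
from .scorefile import FeatureMatrix
from .model import TrainedModel, predict_confidences, train_svm


# ---------------------------------------------------------------- metrics

def precision(truths, predicted_ts) -> float:
    """ts-class precision TP/(TP+FP). truths and predicted_ts are boolean
    (or 0/1) vectors; undefined (no positive predictions) raises."""
    t = np.asarray(truths, dtype=bool)
    p = np.asarray(predicted_ts, dtype=bool)
    if t.shape != p.shape:
        raise InputError("truths and predictions differ in length")
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    if tp + fp == 0:
        raise UndefinedMetricError("no positive predictions: precision undefined")
    return tp / (tp + fp)


def _check_two_class(truths) -> np.ndarray:
    t = np.asarray(truths, dtype=bool)
    if t.all() or not t.any():
        raise UndefinedMetricError("metric undefined for a single-class truth vector")
    return t


def auroc(truths, confidences) -> float:
    """Tie-aware rank AUROC = U/(n₁·n₀) with average ranks (half credit for
    ties)."""
    t = _check_two_class(truths)
    c = np.asarray(confidences, dtype=float)
    if t.shape != c.shape:
        raise InputError("truths and confidences differ in length")
    ranks = rankdata(c)
    n1 = int(t.sum())
    n0 = t.size - n1
    u = ranks[t].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def point_biserial(truths, confidences) -> float:
    """(M₁ − M₀)/s_n · √(p·q) with the population standard deviation s_n;
    equals the Pearson correlation of confidence with 0/1 truth.  Constant
    confidences give 0."""
    t = _check_two_class(truths)
    c = np.asarray(confidences, dtype=float)
    if t.shape != c.shape:
        raise InputError("truths and confidences differ in length")
    s = c.std()  # population (ddof=0)
    if s == 0:
        return 0.0
    p = t.mean()
    q = 1.0 - p
    m1 = c[t].mean()
    m0 = c[~t].mean()
    return float((m1 - m0) / s * np.sqrt(p * q))


def roc_points(truths, confidences) -> np.ndarray:
    """(fpr, tpr) points swept over descending unique confidence thresholds,
    anchored at (0,0) and (1,1)."""
    t = _check_two_class(truths)
    c = np.asarray(confidences, dtype=float)
    order = np.argsort(-c, kind="stable")
    t = t[order]
    c = c[order]
    n1 = t.sum()
    n0 = t.size - n1
    tps = np.cumsum(t)
    fps = np.cumsum(~t)
    # keep only the last point of each tied-confidence block
    last = np.r_[c[1:] != c[:-1], True]
    tpr = np.r_[0.0, tps[last] / n1]
    fpr = np.r_[0.0, fps[last] / n0]
    return np.column_stack([fpr, tpr])


def pr_points(truths, confidences) -> np.ndarray:
    """(recall, precision) points over descending confidence thresholds."""
    t = _check_two_class(truths)
    c = np.asarray(confidences, dtype=float)
    order = np.argsort(-c, kind="stable")
    t = t[order]
    c = c[order]
    n1 = t.sum()
    tps = np.cumsum(t)
    preds = np.arange(1, t.size + 1)
    last = np.r_[c[1:] != c[:-1], True]
    recall = tps[last] / n1
    prec = tps[last] / preds[last]
    return np.column_stack([recall, prec])


def aupr(truths, confidences) -> float:
    """Step-sum area under the precision-recall curve (average precision)."""
    pts = pr_points(truths, confidences)
    recall, prec = pts[:, 0], pts[:, 1]
    prev = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev) * prec))


# ------------------------------------------------------------- CV harness

@dataclass(frozen=True)
class ModelSpec:
    """Classifier variant + hyperparameters for one training run."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: float | None = None


@dataclass
class SplitResult:
    split_id: str
    C: float
    gamma: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    truths: list[int]
    confidences: list[float]


@dataclass
class CVReport:
    scheme: str
    per_split: list[SplitResult]
    aggregate: dict[str, float]
    seeds: list[int] = field(default_factory=list)
    chosen_C: float | None = None
    chosen_gamma: float | None = None

    def to_text(self) -> str:
        payload = {
            "scheme": self.scheme,
            "aggregate": self.aggregate,
            "chosen_C": self.chosen_C,
            "chosen_gamma": self.chosen_gamma,
            "seeds": self.seeds,
            "per_split": [asdict(s) for s in self.per_split],
        }
        return json.dumps(payload, indent=1, default=float) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_text())


def kfold_splits(sample_ids, labels, k: int, seed: int) -> list[list[str]]:
    """k disjoint, label-stratified folds covering every sample; fold sizes
    differ by at most one; deterministic for a given seed."""
    ids = np.asarray(sample_ids)
    y = np.asarray(labels)
    if k > ids.size:
        raise InputError(f"k={k} exceeds the {ids.size} samples")
    if k == ids.size:  # leave-one-out: stratification is vacuous
        rng = np.random.default_rng(seed)
        order = rng.permutation(ids.size)
        return [[str(ids[i])] for i in order]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [[str(s) for s in ids[test]] for _, test in skf.split(ids, y)]


def _confusion(truths: np.ndarray, predicted: np.ndarray) -> tuple[int, int, int, int]:
    tp = int(np.sum(truths & predicted))
    fp = int(np.sum(~truths & predicted))
    tn = int(np.sum(~truths & ~predicted))
    fn = int(np.sum(truths & ~predicted))
    return tp, fp, tn, fn


def _safe_precision(tp: int, fp: int) -> float:
    # a fold that predicts no ts at all scores 0 (conservative), so grid
    # search never rewards the degenerate always-non-ts classifier
    return tp / (tp + fp) if tp + fp > 0 else 0.0


def _run_split(
    m: FeatureMatrix,
    spec: ModelSpec,
    train_ids: list[str],
    test_ids: list[str],
    calibrate: bool,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, TrainedModel]:
    train = FeatureMatrix(m.data.loc[train_ids],
                          m.labels.loc[train_ids] if m.labels is not None else None)
    model = train_svm(train, kernel=spec.kernel, C=spec.C, gamma=spec.gamma,
                      calibrate=calibrate, seed=seed)
    X_test = m.data.loc[test_ids].to_numpy(dtype=float)
    conf = predict_confidences(model, X_test)
    truths = (m.labels.loc[test_ids].to_numpy() == "ts")
    return truths, conf, model


def repeated_cv(
    m: FeatureMatrix,
    spec: ModelSpec,
    k: int = 10,
    reps: int = 10,
    base_seed: int = 0,
    calibrate: bool = True,
) -> CVReport:
    """reps repetitions of stratified k-fold CV with different seeds.

    Metrics are pooled within each repetition; the aggregate reports their
    mean and variance across repetitions plus the overall pooled values."""
    if m.labels is None:
        raise InputError("repeated_cv needs a labelled matrix")
    seeds = [base_seed + r for r in range(reps)]
    per_split: list[SplitResult] = []
    rep_metrics: dict[str, list[float]] = {"precision": [], "auroc": [],
                                           "aupr": [], "point_biserial": []}
    all_truths: list[np.ndarray] = []
    all_conf: list[np.ndarray] = []
    y = m.labels.to_numpy()
    for r, seed in enumerate(seeds):
        folds = kfold_splits(m.sample_ids, y, k, seed)
        rep_truths, rep_conf = [], []
        for f, test_ids in enumerate(folds):
            train_ids = [s for s in m.sample_ids if s not in set(test_ids)]
            truths, conf, _ = _run_split(m, spec, train_ids, test_ids,
                                         calibrate, seed)
            predicted = conf > 0.5
            tp, fp, tn, fn = _confusion(truths, predicted)
            per_split.append(SplitResult(f"rep{r}_fold{f}", spec.C,
                                         spec.gamma, tp, fp, tn, fn,
                                         truths.astype(int).tolist(),
                                         conf.tolist()))
            rep_truths.append(truths)
            rep_conf.append(conf)
        t = np.concatenate(rep_truths)
        c = np.concatenate(rep_conf)
        tp, fp, _, _ = _confusion(t, c > 0.5)
        rep_metrics["precision"].append(_safe_precision(tp, fp))
        rep_metrics["auroc"].append(auroc(t, c))
        rep_metrics["aupr"].append(aupr(t, c))
        rep_metrics["point_biserial"].append(point_biserial(t, c))
        all_truths.append(t)
        all_conf.append(c)
    t = np.concatenate(all_truths)
    c = np.concatenate(all_conf)
    tp, fp, _, _ = _confusion(t, c > 0.5)
    aggregate = {"precision": _safe_precision(tp, fp),
                 "auroc": auroc(t, c),
                 "aupr": aupr(t, c),
                 "point_biserial": point_biserial(t, c)}
    for name, vals in rep_metrics.items():
        aggregate[f"{name}_mean"] = float(np.mean(vals))
        aggregate[f"{name}_var"] = float(np.var(vals))
    return CVReport("10x10fold" if (k, reps) == (10, 10) else f"{reps}x{k}fold",
                    per_split, aggregate, seeds)


DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))


@dataclass
class GridSearchResult:
    c_grid: list[float]
    gamma_grid: list[float]
    surface: np.ndarray  # |C| × |gamma| mean ts precision
    best_C: float
    best_gamma: float | None


def grid_search(
    train_m: FeatureMatrix,
    kernel: str = "rbf",
    c_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    k: int = 10,
    reps: int = 2,
    base_seed: int = 0,
) -> GridSearchResult:
    """Evaluate every (C, γ) lattice point by repeated CV on train_m and
    return the mean ts-precision surface plus its argmax.  Ties break toward
    smaller C, then smaller γ.  Linear kernels ignore the γ axis."""
    c_grid = sorted(float(c) for c in c_grid)
    gammas = sorted(float(g) for g in gamma_grid) if kernel == "rbf" else [None]
    if not c_grid or not gammas:
        raise InputError("hyperparameter grid must be non-empty")
    surface = np.zeros((len(c_grid), len(gammas)))
    best = None
    for i, C in enumerate(c_grid):
        for j, g in enumerate(gammas):
            report = repeated_cv(train_m, ModelSpec(kernel, C, g), k=k,
                                 reps=reps, base_seed=base_seed,
                                 calibrate=False)
            score = report.aggregate["precision_mean"]
            surface[i, j] = score
            if best is None or score > best[0]:
                best = (score, C, g)
    return GridSearchResult(list(c_grid),
                            [g for g in gammas if g is not None],
                            surface, best[1], best[2])


def _log_median(values: list[float]) -> float:
    return float(2.0 ** np.median(np.log2(np.asarray(values, dtype=float))))


def leaveout_cv(
    m: FeatureMatrix,
    kernel: str = "rbf",
    c_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    n_splits: int = 5,
    inner_k: int = 10,
    inner_reps: int = 2,
    base_seed: int = 0,
) -> CVReport:
    """Nested 5× leave-out CV.

    Five disjoint stratified 80/20 splits; each 80% hosts a grid search
    (repeated CV, ts precision), the winner is retrained on the full 80%
    with calibration, and the untouched 20% is scored.  The aggregate pools
    all held-out predictions; chosen_C / chosen_gamma are the log-space
    medians of the five per-split winners."""
    if m.labels is None:
        raise InputError("leaveout_cv needs a labelled matrix")
    y = m.labels.to_numpy()
    folds = kfold_splits(m.sample_ids, y, n_splits, base_seed)
    per_split: list[SplitResult] = []
    chosen_c: list[float] = []
    chosen_g: list[float] = []
    all_truths, all_conf = [], []
    for s, test_ids in enumerate(folds):
        train_ids = [i for i in m.sample_ids if i not in set(test_ids)]
        train = FeatureMatrix(m.data.loc[train_ids], m.labels.loc[train_ids])
        if len(set(train.labels)) < 2:
            import warnings

            warnings.warn(f"leave-out split {s}: single-class training set, skipped")
            continue
        gs = grid_search(train, kernel, c_grid, gamma_grid, k=inner_k,
                         reps=inner_reps, base_seed=base_seed + 100 + s)
        truths, conf, _ = _run_split(m, ModelSpec(kernel, gs.best_C, gs.best_gamma),
                                     train_ids, test_ids, True,
                                     base_seed + 200 + s)
        tp, fp, tn, fn = _confusion(truths, conf > 0.5)
        per_split.append(SplitResult(f"leaveout{s}", gs.best_C, gs.best_gamma,
                                     tp, fp, tn, fn,
                                     truths.astype(int).tolist(), conf.tolist()))
        chosen_c.append(gs.best_C)
        if gs.best_gamma is not None:
            chosen_g.append(gs.best_gamma)
        all_truths.append(truths)
        all_conf.append(conf)
    t = np.concatenate(all_truths)
    c = np.concatenate(all_conf)
    tp = sum(s.tp for s in per_split)
    fp = sum(s.fp for s in per_split)
    aggregate = {"precision": _safe_precision(tp, fp),
                 "auroc": auroc(t, c),
                 "aupr": aupr(t, c),
                 "point_biserial": point_biserial(t, c)}
    return CVReport("5xleaveout" if n_splits == 5 else f"{n_splits}xleaveout",
                    per_split, aggregate, [base_seed],
                    chosen_C=_log_median(chosen_c),
                    chosen_gamma=_log_median(chosen_g) if chosen_g else None)
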