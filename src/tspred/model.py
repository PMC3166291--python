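"""SVM classifiers, confidence calibration, and ranked prediction output.

A two-class soft-margin SVM assigns the ts / non-ts label from the sign of

    f(x) = Σ_i α_i y_i K(x_i, x) + b

over the support vectors x_i.  The linear kernel K(u, v) = u·v collapses to
an explicit weight vector w = Σ_i α_i y_i x_i (which is what makes SVM-LIN
interpretable); the RBF kernel K(u, v) = exp(−γ‖u − v‖²) yields the
non-linear boundaries needed to isolate an intermediate destabilization
band.  Features are min-max scaled to [0, 1] on the training data before
fitting.  Margins are mapped to confidences by a slope-only Platt sigmoid
fitted on out-of-fold margins, so confidence > 0.5 exactly when the
predicted label is ts.

scikit-learn's SVC performs the quadratic-programming fit; everything the
model needs for re-scoring (support vectors, dual coefficients, bias,
scaling, calibration) is copied into the TrainedModel, and decision values
are recomputed from those fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import InputError, TsPredError
from .scorefile import FeatureMatrix

KERNELS = ("linear", "rbf")

# Sequence-derived feature names (SVM-seq keeps exactly these)
SEQUENCE_FEATURES = (
    "aminochange", "aminochange2",
    "pssm_mut", "pssm_nat", "pssm_diff",
    "freq_mut", "freq_nat", "freq_diff",
    "info_cont",
)


@dataclass
class TrainedModel:
    kernel: str
    C: float
    gamma: float | None
    feature_names: list[str]
    scale_min: np.ndarray      # per-feature training minimum
    scale_range: np.ndarray    # per-feature training range (0 for constants)
    support_vectors: np.ndarray  # scaled space, n_sv × n_features
    dual_coefs: np.ndarray       # α_i·y_i per support vector
    bias: float
    calibration_slope: float = 1.0  # p = σ(slope · margin)

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise InputError(f"unknown kernel {self.kernel!r}")
        if len(self.dual_coefs) != len(self.support_vectors) or len(self.dual_coefs) < 1:
            raise InputError("support vectors and dual coefficients must align")
        if self.support_vectors.shape[1] != len(self.feature_names):
            raise InputError("support-vector width must match feature_names")

    def scale(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        with np.errstate(invalid="ignore"):
            scaled = (x - self.scale_min) / np.where(self.scale_range > 0,
                                                     self.scale_range, 1.0)
        return scaled

    def weight_vector(self) -> np.ndarray:
        """Explicit w = Σ α_i y_i x_i; linear kernel only."""
        if self.kernel != "linear":
            raise TsPredError("explicit weights are defined only for linear kernels")
        return self.dual_coefs @ self.support_vectors


@dataclass(frozen=True)
class Prediction:
    mutation_id: str
    confidence: float
    rank: int


def _kernel_matrix(model: TrainedModel, x_scaled: np.ndarray) -> np.ndarray:
    sv = model.support_vectors
    if model.kernel == "linear":
        return sv @ x_scaled
    d2 = np.sum((sv - x_scaled) ** 2, axis=1)
    return np.exp(-model.gamma * d2)


def decision_value(model: TrainedModel, x: np.ndarray) -> float:
    """Margin f(x) recomputed from the stored support-vector expansion."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(model.feature_names),):
        raise InputError(
            f"feature vector has shape {x.shape}, expected ({len(model.feature_names)},)"
        )
    xs = model.scale(x)
    return float(model.dual_coefs @ _kernel_matrix(model, xs) + model.bias)


def decision_values(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    """Vectorized margins for an n × n_features matrix."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(model.feature_names):
        raise InputError(
            f"feature block has shape {X.shape}, "
            f"expected (*, {len(model.feature_names)})"
        )
    Xs = model.scale(X)
    sv = model.support_vectors
    if model.kernel == "linear":
        K = Xs @ sv.T
    else:
        d2 = ((Xs[:, None, :] - sv[None, :, :]) ** 2).sum(axis=2)
        K = np.exp(-model.gamma * d2)
    return K @ model.dual_coefs + model.bias


def predict_confidences(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    m = decision_values(model, X)
    return 1.0 / (1.0 + np.exp(-model.calibration_slope * m))


def predict_confidence(model: TrainedModel, x: np.ndarray) -> float:
    """Confidence in (0, 1); strictly increasing in the margin and > 0.5
    exactly when the predicted label is ts."""
    m = decision_value(model, x)
    return float(1.0 / (1.0 + np.exp(-model.calibration_slope * m)))


def _fit_calibration_slope(margins: np.ndarray, y: np.ndarray) -> float:
    """Slope-only Platt fit: maximize the Bernoulli likelihood of
    p = σ(a·m) over a > 0.  Closed-form-free but 1-D, solved by golden-ratio
    refinement on the log-likelihood over a log-spaced bracket."""
    t = (y > 0).astype(float)

    def nll(a: float) -> float:
        z = np.clip(a * margins, -500, 500)
        p = 1.0 / (1.0 + np.exp(-z))
        eps = 1e-12
        return -float(np.sum(t * np.log(p + eps) + (1 - t) * np.log(1 - p + eps)))

    grid = np.logspace(-2, 2, 41)
    best = min(grid, key=nll)
    lo, hi = best / 2, best * 2
    for _ in range(60):
        m1 = lo + (hi - lo) * 0.382
        m2 = lo + (hi - lo) * 0.618
        if nll(m1) <= nll(m2):
            hi = m2
        else:
            lo = m1
    a = (lo + hi) / 2
    return float(a) if a > 0 else 1.0


def train_svm(
    m: FeatureMatrix,
    kernel: str = "rbf",
    C: float = 1.0,
    gamma: float | None = None,
    calibrate: bool = True,
    calibration_folds: int = 3,
    seed: int = 0,
) -> TrainedModel:
    """Fit a soft-margin SVM on min-max-scaled features.

    gamma is required for the RBF kernel (default 1/n_features if omitted).
    With calibrate=True the Platt slope is fitted on out-of-fold margins
    from a stratified internal split; otherwise the slope defaults to 1.
    """
    if kernel not in KERNELS:
        raise InputError(f"unknown kernel {kernel!r}")
    if C <= 0:
        raise InputError("C must be > 0")
    X = m.data.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise InputError("feature matrix contains non-finite values")
    y = m.label_array()
    if len(set(y)) < 2:
        raise TsPredError("training requires both ts and non-ts samples")
    if kernel == "rbf":
        gamma = float(gamma) if gamma is not None else 1.0 / X.shape[1]
        if gamma <= 0:
            raise InputError("gamma must be > 0 for the RBF kernel")
    else:
        gamma = None

    mins = X.min(axis=0)
    ranges = X.max(axis=0) - mins
    Xs = (X - mins) / np.where(ranges > 0, ranges, 1.0)

    def fit(Xt: np.ndarray, yt: np.ndarray) -> SVC:
        svc = SVC(kernel=kernel, C=C, gamma=gamma if gamma is not None else "scale")
        svc.fit(Xt, yt)
        return svc

    svc = fit(Xs, y)
    slope = 1.0
    if calibrate:
        n_splits = min(calibration_folds, int(np.bincount((y > 0).astype(int)).min()))
        if n_splits >= 2:
            margins, truths = [], []
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            for tr, te in skf.split(Xs, y):
                if len(set(y[tr])) < 2:
                    continue
                fold = fit(Xs[tr], y[tr])
                margins.append(fold.decision_function(Xs[te]))
                truths.append(y[te])
            if margins:
                slope = _fit_calibration_slope(
                    np.concatenate(margins), np.concatenate(truths)
                )

    return TrainedModel(
        kernel=kernel,
        C=float(C),
        gamma=gamma,
        feature_names=m.feature_names,
        scale_min=mins,
        scale_range=ranges,
        support_vectors=svc.support_vectors_.copy(),
        dual_coefs=svc.dual_coef_[0].copy(),
        bias=float(svc.intercept_[0]),
        calibration_slope=slope,
    )


def predict_label(model: TrainedModel, x: np.ndarray) -> str:
    return "ts" if decision_value(model, x) > 0 else "non-ts"


def rank_predictions(model: TrainedModel, candidates: FeatureMatrix) -> list[Prediction]:
    """Confidence-ranked predictions for a candidate matrix whose sample ids
    are mutation ids.  Ties in confidence break by id, ascending."""
    matrix = candidates.select(model.feature_names)
    scored = [
        (predict_confidence(model, matrix.data.loc[sid].to_numpy(dtype=float)), sid)
        for sid in matrix.sample_ids
    ]
    scored.sort(key=lambda t: (-t[0], t[1]))
    return [
        Prediction(mutation_id=sid, confidence=conf, rank=i + 1)
        for i, (conf, sid) in enumerate(scored)
    ]


def top_k(predictions: list[Prediction], k: int = 5) -> list[Prediction]:
    return predictions[:k]


def format_predictions(predictions: list[Prediction]) -> str:
    """The ranked-list text format: header then one line per prediction,
    e.g. ``1  0.839 YBR109C-F140_GLY_Scer``."""
    lines = ["rank conf id"]
    for p in predictions:
        lines.append(f"{p.rank}  {p.confidence:.3f} {p.mutation_id}")
    return "\n".join(lines) + "\n"


def svm_seq_view(m: FeatureMatrix) -> FeatureMatrix:
    """Restrict a matrix to sequence-derived features only (the SVM-seq
    variant's input): category-change codes and PSSM statistics.  All
    Rosetta-derived and structure features (ACCP, ss_*) are dropped."""
    kept = [n for n in m.feature_names if n in SEQUENCE_FEATURES]
    if not kept:
        raise InputError("matrix has no sequence-derived features")
    return m.select(kept)


def feature_weights(model: TrainedModel) -> list[tuple[str, float]]:
    """(feature, signed weight) sorted by |weight| descending; linear only."""
    w = model.weight_vector()
    order = sorted(range(len(w)), key=lambda i: (-abs(w[i]), model.feature_names[i]))
    return [(model.feature_names[i], float(w[i])) for i in order]


def save_model(model: TrainedModel, path: str | Path) -> None:
    payload = {
        "kernel": model.kernel,
        "C": model.C,
        "gamma": model.gamma,
        "feature_names": model.feature_names,
        "scale_min": model.scale_min.tolist(),
        "scale_range": model.scale_range.tolist(),
        "support_vectors": model.support_vectors.tolist(),
        "dual_coefs": model.dual_coefs.tolist(),
        "bias": model.bias,
        "calibration_slope": model.calibration_slope,
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def load_model(path: str | Path) -> TrainedModel:
    payload = json.loads(Path(path).read_text())
    return TrainedModel(
        kernel=payload["kernel"],
        C=payload["C"],
        gamma=payload["gamma"],
        feature_names=payload["feature_names"],
        scale_min=np.array(payload["scale_min"], dtype=float),
        scale_range=np.array(payload["scale_range"], dtype=float),
        support_vectors=np.array(payload["support_vectors"], dtype=float),
        dual_coefs=np.array(payload["dual_coefs"], dtype=float),
        bias=payload["bias"],
        calibration_slope=payload["calibration_slope"],
    )
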