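"""Four-class macule classifier.

A small feedforward network — 11 inputs, two hidden layers of 4 neurons
with hyperbolic-tangent activations, and 4 logistic output units — is
trained against one-hot targets by minimizing the sum of squared errors
with the Levenberg–Marquardt (LM) algorithm: damped Gauss–Newton steps
``(J'J + λI) δ = -J'r`` on the residual vector ``r = outputs - targets``,
with the Jacobian ``J`` assembled by backpropagation.  λ shrinks after
every accepted step (toward Gauss–Newton) and grows after a rejected one
(toward small gradient steps), so the training loss is non-increasing
across accepted steps.

Features are z-scored with training-split statistics before entering the
network.  Evaluation reports a 4x4 confusion matrix, accuracy, and the
Pearson correlation R between the flattened one-hot targets and the raw
network outputs.

A BFGS-based trainer is available behind the same interface as a
robustness fallback; LM is the default and the reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from .features import CLASS_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "LAYER_SIZES",
    "NetworkParams",
    "TrainConfig",
    "FitReport",
    "standardize",
    "stratified_split",
    "init_params",
    "forward",
    "predict",
    "train_network",
    "evaluate",
]

#: Layer widths of the reference architecture (input, hidden, hidden, output).
LAYER_SIZES = (11, 4, 4, 4)


@dataclass
class NetworkParams:
    """Weights, biases and standardization constants of a trained network."""

    weights: list[np.ndarray]  # [(4,11), (4,4), (4,4)]
    biases: list[np.ndarray]  # [(4,), (4,), (4,)]
    feature_mean: np.ndarray | None = None
    feature_std: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "layer_sizes": list(LAYER_SIZES),
            "activations": ["tanh", "tanh", "logistic"],
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feature_mean": None
            if self.feature_mean is None
            else self.feature_mean.tolist(),
            "feature_std": None
            if self.feature_std is None
            else self.feature_std.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkParams":
        return cls(
            weights=[np.asarray(w, dtype=float) for w in d["weights"]],
            biases=[np.asarray(b, dtype=float) for b in d["biases"]],
            feature_mean=None
            if d.get("feature_mean") is None
            else np.asarray(d["feature_mean"], dtype=float),
            feature_std=None
            if d.get("feature_std") is None
            else np.asarray(d["feature_std"], dtype=float),
        )


@dataclass
class TrainConfig:
    train_fraction: float = 0.60
    lambda0: float = 1e-3
    lambda_factor: float = 10.0
    lambda_max: float = 1e10
    max_epochs: int = 200
    tol: float = 1e-9
    n_restarts: int = 3
    optimizer: str = "lm"  # "lm" or "bfgs"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


@dataclass
class FitReport:
    confusion: np.ndarray  # 4x4, rows = true class, cols = predicted
    accuracy: float  # percent
    regression_r: float  # Pearson R, flattened targets vs outputs
    n_evaluated: int
    train_sse: float = float("nan")
    accuracy_all: float = float("nan")  # accuracy over train + test pooled

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.confusion.tolist(),
            "class_order": list(CLASS_NAMES),
            "accuracy_percent": self.accuracy,
            "accuracy_all_percent": self.accuracy_all,
            "regression_r": self.regression_r,
            "n_evaluated": self.n_evaluated,
            "train_sse": self.train_sse,
        }


# ---------------------------------------------------------------- plumbing


def standardize(
    train: np.ndarray, apply_to: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """z-score ``apply_to`` with the mean/SD of ``train``.

    Features with zero SD are centered but not scaled.  Returns
    ``(transformed, mean, std)``; the statistics never see test labels.
    """
    train = np.asarray(train, dtype=float)
    if train.size == 0:
        raise ValueError("empty training matrix")
    mean = train.mean(axis=0)
    std = train.std(axis=0)
    safe = np.where(std > 0, std, 1.0)
    return (np.asarray(apply_to, dtype=float) - mean) / safe, mean, safe


def stratified_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class shuffled split; returns (train_idx, test_idx)."""
    labels = np.asarray(labels)
    train_idx, test_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        n_train = int(round(train_fraction * idx.size))
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return np.concatenate(train_idx), np.concatenate(test_idx)


def init_params(rng: np.random.Generator, scale: float = 0.5) -> NetworkParams:
    """Small uniform random weights in [-scale, scale]."""
    weights, biases = [], []
    for n_in, n_out in zip(LAYER_SIZES[:-1], LAYER_SIZES[1:]):
        weights.append(rng.uniform(-scale, scale, size=(n_out, n_in)))
        biases.append(rng.uniform(-scale, scale, size=n_out))
    return NetworkParams(weights=weights, biases=biases)


def _logistic(z: np.ndarray) -> np.ndarray:
    return special.expit(z)


def forward(
    params: NetworkParams, x: np.ndarray, return_hidden: bool = False
):
    """Forward pass on standardized inputs of shape (n, 11) or (11,).

    tanh on both hidden layers, logistic on the output layer.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[1] != LAYER_SIZES[0]:
        raise ValueError(f"expected {LAYER_SIZES[0]} features, got {x.shape[1]}")
    w1, w2, w3 = params.weights
    b1, b2, b3 = params.biases
    a1 = np.tanh(x @ w1.T + b1)
    a2 = np.tanh(a1 @ w2.T + b2)
    y = _logistic(a2 @ w3.T + b3)
    if return_hidden:
        return y, (x, a1, a2)
    return y


def predict(params: NetworkParams, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class indices (argmax of the 4 outputs; ties -> lowest index) + activations."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if params.feature_mean is not None:
        x = (x - params.feature_mean) / params.feature_std
    y = forward(params, x)
    return np.argmax(y, axis=1), y


# ---------------------------------------------------- Levenberg–Marquardt


def _pack(params: NetworkParams) -> np.ndarray:
    return np.concatenate(
        [w.ravel() for w in params.weights] + [b.ravel() for b in params.biases]
    )


def _unpack(theta: np.ndarray) -> NetworkParams:
    shapes = [(o, i) for i, o in zip(LAYER_SIZES[:-1], LAYER_SIZES[1:])]
    weights, biases = [], []
    pos = 0
    for shape in shapes:
        size = shape[0] * shape[1]
        weights.append(theta[pos : pos + size].reshape(shape))
        pos += size
    for shape in shapes:
        biases.append(theta[pos : pos + shape[0]])
        pos += shape[0]
    return NetworkParams(weights=weights, biases=biases)


def _residuals_and_jacobian(
    theta: np.ndarray, x: np.ndarray, targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals r = y - t (flattened) and their Jacobian by backprop.

    One Jacobian row per (sample, output unit) pair; columns follow the
    packing order of :func:`_pack`.
    """
    params = _unpack(theta)
    w2, w3 = params.weights[1], params.weights[2]
    y, (x0, a1, a2) = forward(params, x, return_hidden=True)
    n = x0.shape[0]
    n_out = LAYER_SIZES[-1]
    residuals = (y - targets).ravel()

    jac = np.empty((n * n_out, theta.size))
    dy = y * (1.0 - y)  # logistic derivative, shape (n, 4)
    da2 = 1.0 - a2**2
    da1 = 1.0 - a1**2
    row = 0
    for i in range(n):
        for k in range(n_out):
            v3 = np.zeros(n_out)
            v3[k] = dy[i, k]
            v2 = (w3.T @ v3) * da2[i]
            v1 = (w2.T @ v2) * da1[i]
            jac[row] = np.concatenate(
                [
                    np.outer(v1, x0[i]).ravel(),
                    np.outer(v2, a1[i]).ravel(),
                    np.outer(v3, a2[i]).ravel(),
                    v1,
                    v2,
                    v3,
                ]
            )
            row += 1
    return residuals, jac


def _train_lm(
    x: np.ndarray, targets: np.ndarray, theta0: np.ndarray, cfg: TrainConfig
) -> tuple[np.ndarray, float]:
    """Damped Gauss–Newton loop; returns (theta, final SSE)."""
    theta = theta0.copy()
    lam = cfg.lambda0
    r, jac = _residuals_and_jacobian(theta, x, targets)
    sse = float(r @ r)
    identity = np.eye(theta.size)
    for _ in range(cfg.max_epochs):
        grad = jac.T @ r
        if np.linalg.norm(grad, ord=np.inf) < cfg.tol:
            break
        hess = jac.T @ jac
        accepted = False
        while lam <= cfg.lambda_max:
            try:
                step = np.linalg.solve(hess + lam * identity, -grad)
            except np.linalg.LinAlgError:
                lam *= cfg.lambda_factor
                continue
            trial = theta + step
            r_trial, jac_trial = _residuals_and_jacobian(trial, x, targets)
            sse_trial = float(r_trial @ r_trial)
            if sse_trial < sse:
                theta, r, jac, sse = trial, r_trial, jac_trial, sse_trial
                lam = max(lam / cfg.lambda_factor, 1e-12)
                accepted = True
                break
            lam *= cfg.lambda_factor
        if not accepted:
            break
    return theta, sse


def _train_bfgs(
    x: np.ndarray, targets: np.ndarray, theta0: np.ndarray, cfg: TrainConfig
) -> tuple[np.ndarray, float]:
    """Quasi-Newton fallback on the same SSE objective."""

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        r, jac = _residuals_and_jacobian(theta, x, targets)
        return float(r @ r), 2.0 * (jac.T @ r)

    res = optimize.minimize(
        objective, theta0, jac=True, method="BFGS",
        options={"maxiter": cfg.max_epochs, "gtol": cfg.tol},
    )
    return res.x, float(res.fun)


def train_network(
    features: np.ndarray, labels: np.ndarray, cfg: TrainConfig | None = None
) -> tuple[NetworkParams, FitReport]:
    """Train the 11-4-4-4 network and evaluate on a held-out split.

    ``labels`` are integer class indices in [0, 4).  The data are split
    60/40 stratified by class (seeded), features are z-scored with
    training statistics, and the network minimizing training SSE over
    ``cfg.n_restarts`` random initializations is kept.  The report is
    computed on the held-out split.
    """
    cfg = cfg or TrainConfig()
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    if features.ndim != 2 or features.shape[1] != LAYER_SIZES[0]:
        raise ValueError(f"expected (n, {LAYER_SIZES[0]}) feature matrix")
    counts = np.bincount(labels, minlength=len(CLASS_NAMES))
    if (counts < 2).any():
        raise ValueError("need at least 2 examples per class")

    rng = np.random.default_rng(cfg.seed)
    train_idx, test_idx = stratified_split(labels, cfg.train_fraction, rng)
    x_train, mean, std = standardize(features[train_idx], features[train_idx])
    t_train = np.eye(len(CLASS_NAMES))[labels[train_idx]]

    trainer = _train_lm if cfg.optimizer == "lm" else _train_bfgs
    best_theta, best_sse = None, np.inf
    for _ in range(max(cfg.n_restarts, 1)):
        theta0 = _pack(init_params(rng))
        theta, sse = trainer(x_train, t_train, theta0, cfg)
        if sse < best_sse:
            best_theta, best_sse = theta, sse
    logger.info("training SSE after %s: %.6g", cfg.optimizer.upper(), best_sse)

    params = _unpack(best_theta)
    params.feature_mean = mean
    params.feature_std = std
    report = evaluate(params, features[test_idx], labels[test_idx])
    report.train_sse = best_sse
    # Accuracy over the pooled 40 vectors is also of interest when the
    # split is small; reported alongside, never used for model selection.
    pred_all, _ = predict(params, features)
    report.accuracy_all = 100.0 * float((pred_all == labels).mean())
    return params, report


def evaluate(
    params: NetworkParams, features: np.ndarray, labels: np.ndarray
) -> FitReport:
    """Confusion matrix, accuracy % and target/output Pearson R on a test set."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.shape[0] == 0:
        raise ValueError("empty evaluation set")
    pred, outputs = predict(params, features)
    targets = np.eye(len(CLASS_NAMES))[labels]
    confusion = _sk_confusion_matrix(
        labels, pred, labels=range(len(CLASS_NAMES))
    )
    accuracy = 100.0 * float((pred == labels).mean())
    t_flat, y_flat = targets.ravel(), outputs.ravel()
    if np.std(y_flat) == 0.0 or np.std(t_flat) == 0.0:
        regression_r = 0.0
    else:
        regression_r = float(np.corrcoef(t_flat, y_flat)[0, 1])
    return FitReport(
        confusion=confusion,
        accuracy=accuracy,
        regression_r=regression_r,
        n_evaluated=labels.size,
    )
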