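"""Multilayer perceptron gesture classifier with Levenberg-Marquardt training.

The reference architecture is a fully connected 20-15-5 network: 20 inputs
(the hybrid feature vector), 15 logistic-sigmoid hidden units, 5 logistic
outputs — one per gesture — trained on one-hot targets with a mean-squared
error objective.  The predicted gesture is the argmax output.

Training functions
------------------
``lm``    Levenberg-Marquardt: damped Gauss-Newton on the residual Jacobian,
          solving (J'J + mu*I) dtheta = -J'r; mu is multiplied by mu_inc when a
          step raises the training MSE (step rejected) and by mu_dec when it is
          accepted, interpolating between gradient descent and Gauss-Newton.
``bfgs``  BFGS quasi-Newton with backtracking line search.
``cgp``   Polak-Ribiere conjugate gradient (non-negative beta, periodic
          restarts every n_params iterations).
``oss``   One-step secant: a memoryless quasi-Newton direction built from the
          last parameter and gradient differences.
``gdx``   Gradient descent with momentum and an adaptive learning rate
          (rate grows on improvement, shrinks — and the step is rejected —
          when the MSE grows by more than 4%).

All trainers share batch epochs, early stopping on consecutive validation
failures, and return the model snapshot at the best validation epoch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .acquire import split_indices
from .errors import ParameterError
from .features import FeatureDataset, Standardizer

__all__ = [
    "MLPModel",
    "TrainHyper",
    "TrainingReport",
    "DataSplit",
    "EarlyStopping",
    "ALGORITHMS",
    "init_model",
    "forward",
    "predict",
    "one_hot",
    "mse",
    "jacobian",
    "gradient",
    "train",
    "compare_training_functions",
    "make_split",
    "accuracy_percent",
    "save_model",
    "load_model",
]

ALGORITHMS = ("lm", "bfgs", "cgp", "oss", "gdx")
ALGORITHM_LABELS = {
    "lm": "Levenberg-Marquardt",
    "bfgs": "BFGS Quasi-Newton",
    "cgp": "Polak-Ribiere Conjugate Gradient",
    "oss": "One Step Secant",
    "gdx": "Variable Learning Rate Backpropagation",
}


def _activate(s: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return expit(s)
    if kind == "identity":
        return s
    raise ParameterError(f"unknown activation {kind!r}")


def _activate_deriv(a: np.ndarray, kind: str) -> np.ndarray:
    # derivative expressed through the activation value
    if kind == "logistic":
        return a * (1.0 - a)
    if kind == "identity":
        return np.ones_like(a)
    raise ParameterError(f"unknown activation {kind!r}")


@dataclass
class MLPModel:
    """Feed-forward network: weights[l] maps layer l activations to layer l+1."""

    sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activations: tuple[str, ...]
    seed: int | None = None

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def copy(self) -> "MLPModel":
        return MLPModel(self.sizes, [w.copy() for w in self.weights],
                        [b.copy() for b in self.biases], self.activations, self.seed)


def init_model(seed: int, sizes: Sequence[int] = (20, 15, 5),
               activations: Sequence[str] | None = None) -> MLPModel:
    """Reproducible initialization: zero biases, weights ~ N(0, 1/fan_in)."""
    sizes = tuple(int(s) for s in sizes)
    if len(sizes) < 2:
        raise ParameterError("network needs at least input and output layers")
    if activations is None:
        activations = ("logistic",) * (len(sizes) - 1)
    activations = tuple(activations)
    if len(activations) != len(sizes) - 1:
        raise ParameterError("one activation per non-input layer required")
    rng = np.random.default_rng(seed)
    weights = [rng.normal(0.0, 1.0 / np.sqrt(sizes[l]), size=(sizes[l + 1], sizes[l]))
               for l in range(len(sizes) - 1)]
    biases = [np.zeros(sizes[l + 1]) for l in range(len(sizes) - 1)]
    return MLPModel(sizes, weights, biases, activations, seed=seed)


def _forward_all(model: MLPModel, X: np.ndarray) -> list[np.ndarray]:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.sizes[0]:
        raise ParameterError(
            f"input has {X.shape[1]} features, model expects {model.sizes[0]}")
    acts = [X]
    for W, b, kind in zip(model.weights, model.biases, model.activations):
        acts.append(_activate(acts[-1] @ W.T + b, kind))
    return acts


def forward(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Network outputs, shape (n_cases, n_outputs)."""
    return _forward_all(model, X)[-1]


def predict(model: MLPModel, X: np.ndarray) -> np.ndarray:
    """Predicted class ids (argmax output; ties go to the lowest id)."""
    return np.argmax(forward(model, X), axis=1)


def one_hot(labels: Sequence[int], n_classes: int = 5) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    Z = np.zeros((labels.size, n_classes))
    Z[np.arange(labels.size), labels] = 1.0
    return Z


def residuals(model: MLPModel, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Per-case, per-output residuals e = z - y, shape (n_cases, n_outputs)."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    Y = forward(model, X)
    if Z.shape != Y.shape:
        raise ParameterError(f"target shape {Z.shape} != output shape {Y.shape}")
    return Z - Y


def mse(model: MLPModel, X: np.ndarray, Z: np.ndarray) -> float:
    """Mean squared residual over all outputs and cases."""
    return float(np.mean(residuals(model, X, Z) ** 2))


def _pack(model: MLPModel) -> np.ndarray:
    return np.concatenate([np.concatenate([w.ravel(), b])
                           for w, b in zip(model.weights, model.biases)])


def _unpack(model: MLPModel, theta: np.ndarray) -> MLPModel:
    out = model.copy()
    pos = 0
    for l, (w, b) in enumerate(zip(out.weights, out.biases)):
        out.weights[l] = theta[pos:pos + w.size].reshape(w.shape)
        pos += w.size
        out.biases[l] = theta[pos:pos + b.size]
        pos += b.size
    return out


def jacobian(model: MLPModel, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Jacobian of the flattened residual vector w.r.t. the packed parameters.

    Shape (n_cases * n_outputs, n_params); rows follow C order of the
    residual matrix, columns follow the pack order [W1, b1, W2, b2, ...].
    Computed by backpropagating one sensitivity per output unit.
    """
    acts = _forward_all(model, X)
    n = acts[0].shape[0]
    n_out = model.sizes[-1]
    L = len(model.weights)
    # G[l][n, o, j] = d y_o / d s_l[j]  (s_l = pre-activation of layer l+1)
    out_deriv = _activate_deriv(acts[-1], model.activations[-1])  # (n, out)
    G = np.zeros((n, n_out, n_out))
    idx = np.arange(n_out)
    G[:, idx, idx] = out_deriv
    blocks: list[np.ndarray] = []  # per layer, reversed order
    for l in range(L - 1, -1, -1):
        a_prev = acts[l]
        dW = np.einsum("noj,ni->noji", G, a_prev).reshape(n, n_out, -1)
        db = G.copy()
        blocks.append(np.concatenate([dW, db], axis=2))
        if l > 0:
            G = np.einsum("noj,ji->noi", G, model.weights[l])
            G *= _activate_deriv(acts[l], model.activations[l - 1])[:, None, :]
    dY = np.concatenate(blocks[::-1], axis=2)  # (n, out, P)
    return -dY.reshape(n * n_out, model.n_params)


def gradient(model: MLPModel, X: np.ndarray, Z: np.ndarray) -> np.ndarray:
    """Gradient of the MSE w.r.t. the packed parameters."""
    r = residuals(model, X, Z).ravel()
    J = jacobian(model, X, Z)
    return 2.0 * (J.T @ r) / r.size


@dataclass(frozen=True)
class TrainHyper:
    """Training hyper-parameters (shared across the five algorithms)."""

    algorithm: str = "lm"
    max_epochs: int = 1000
    goal_mse: float = 0.0
    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    lr0: float = 0.01
    lr_inc: float = 1.05
    lr_dec: float = 0.7
    momentum: float = 0.9
    max_perf_inc: float = 1.04
    max_validation_failures: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ParameterError(f"algorithm must be one of {ALGORITHMS}")
        if not (self.mu_inc > 1.0 > self.mu_dec > 0.0):
            raise ParameterError("LM damping requires mu_inc > 1 > mu_dec > 0")
        if min(self.mu0, self.lr0, self.lr_inc, self.lr_dec) <= 0:
            raise ParameterError("rates must be positive")


@dataclass
class DataSplit:
    """Standardized feature arrays (cases x features) and integer labels."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    X_test: np.ndarray | None = None
    y_test: np.ndarray | None = None


def make_split(dataset: FeatureDataset, fractions: Sequence[float],
               seed: int, standardize: bool = True,
               ) -> tuple[DataSplit, Standardizer | None]:
    """Stratified split of a feature dataset into train/val(/test) arrays.

    The standardizer is fit on the training split only and applied everywhere.
    """
    if len(fractions) not in (2, 3):
        raise ParameterError("fractions must define 2 (train/val) or 3 subsets")
    parts = split_indices(dataset.labels, fractions, seed)
    scaler: Standardizer | None = None
    X = dataset.X
    if standardize:
        scaler = Standardizer().fit(X[:, parts[0]])
        X = scaler.transform(X)
    arrays = [(X[:, p].T, dataset.labels[p]) for p in parts]
    split = DataSplit(*arrays[0], *arrays[1],
                      *(arrays[2] if len(arrays) == 3 else (None, None)))
    return split, scaler


class EarlyStopping:
    """Stop after ``patience`` consecutive epochs without a validation improvement."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.failures = 0

    def update(self, epoch: int, val_mse: float) -> bool:
        """Record one epoch; return True when training should stop."""
        if val_mse < self.best:
            self.best = val_mse
            self.best_epoch = epoch
            self.failures = 0
        else:
            self.failures += 1
        return self.failures >= self.patience


@dataclass
class TrainingReport:
    """Per-epoch error curves and the best-validation snapshot."""

    algorithm: str
    train_curve: list[float]
    val_curve: list[float]
    test_curve: list[float]
    best_epoch: int
    best_val_mse: float
    stop_reason: str
    model: MLPModel
    accuracies: dict = field(default_factory=dict)

    def summary(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "algorithm_label": ALGORITHM_LABELS[self.algorithm],
            "epochs": len(self.train_curve) - 1,
            "best_epoch": self.best_epoch,
            "best_val_mse": self.best_val_mse,
            "stop_reason": self.stop_reason,
            **{f"{k}_accuracy_percent": v for k, v in self.accuracies.items()},
        }

    def curves_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"epoch": range(len(self.train_curve)),
                             "train_mse": self.train_curve,
                             "val_mse": self.val_curve,
                             "test_mse": self.test_curve if self.test_curve
                             else [np.nan] * len(self.train_curve)})


def accuracy_percent(model: MLPModel, X: np.ndarray, y: Sequence[int]) -> float:
    return float(100.0 * np.mean(predict(model, X) == np.asarray(y)))


def _backtrack(f: Callable[[np.ndarray], float], theta: np.ndarray, fval: float,
               g: np.ndarray, d: np.ndarray, alpha0: float = 1.0,
               c1: float = 1e-4, shrink: float = 0.5,
               max_halvings: int = 40) -> tuple[float | None, float]:
    """Armijo backtracking line search along descent direction d."""
    gd = float(g @ d)
    if gd >= 0:
        return None, fval
    alpha = alpha0
    for _ in range(max_halvings):
        fnew = f(theta + alpha * d)
        if np.isfinite(fnew) and fnew <= fval + c1 * alpha * gd:
            return alpha, fnew
        alpha *= shrink
    return None, fval


class _LMState:
    def __init__(self, hyper: TrainHyper):
        self.mu = hyper.mu0

    def step(self, model: MLPModel, theta: np.ndarray, fval: float,
             X: np.ndarray, Z: np.ndarray, hyper: TrainHyper,
             ) -> tuple[np.ndarray | None, float, str | None]:
        r = residuals(_unpack(model, theta), X, Z).ravel()
        J = jacobian(_unpack(model, theta), X, Z)
        JtJ = J.T @ J
        Jtr = J.T @ r
        eye = np.eye(theta.size)
        while self.mu <= hyper.mu_max:
            try:
                delta = np.linalg.solve(JtJ + self.mu * eye, -Jtr)
            except np.linalg.LinAlgError:
                self.mu *= hyper.mu_inc
                continue
            cand = theta + delta
            fnew = mse(_unpack(model, cand), X, Z)
            if np.isfinite(fnew) and fnew < fval:
                self.mu = max(self.mu * hyper.mu_dec, 1e-20)
                return cand, fnew, None
            self.mu *= hyper.mu_inc
        return None, fval, "mu_max"


class _GradState:
    """Shared state for the gradient-based trainers (bfgs / cgp / oss / gdx)."""

    def __init__(self, hyper: TrainHyper, n_params: int):
        self.lr = hyper.lr0
        self.velocity = np.zeros(n_params)
        self.H: np.ndarray | None = None       # BFGS inverse Hessian
        self.g_prev: np.ndarray | None = None
        self.d_prev: np.ndarray | None = None
        self.theta_prev: np.ndarray | None = None
        self.iters_since_restart = 0

    # -- direction builders ------------------------------------------------
    def _dir_bfgs(self, g: np.ndarray) -> np.ndarray:
        if self.H is None:
            self.H = np.eye(g.size)
        return -(self.H @ g)

    def _dir_cgp(self, g: np.ndarray, n_params: int) -> np.ndarray:
        if (self.g_prev is None or self.d_prev is None
                or self.iters_since_restart >= n_params):
            self.iters_since_restart = 0
            return -g
        beta = max(0.0, float(g @ (g - self.g_prev)) / float(self.g_prev @ self.g_prev))
        d = -g + beta * self.d_prev
        if g @ d >= 0:  # not a descent direction: restart
            self.iters_since_restart = 0
            return -g
        return d

    def _dir_oss(self, g: np.ndarray, theta: np.ndarray) -> np.ndarray:
        if self.g_prev is None or self.theta_prev is None:
            return -g
        s = theta - self.theta_prev
        y = g - self.g_prev
        sy = float(s @ y)
        if abs(sy) < 1e-12:
            return -g
        A = -(1.0 + float(y @ y) / sy) * float(g @ s) / sy + float(g @ y) / sy
        B = float(g @ s) / sy
        d = -g + A * s + B * y
        return d if g @ d < 0 else -g

    def step(self, algorithm: str, model: MLPModel, theta: np.ndarray, fval: float,
             X: np.ndarray, Z: np.ndarray, hyper: TrainHyper,
             ) -> tuple[np.ndarray | None, float, str | None]:
        f = lambda th: mse(_unpack(model, th), X, Z)
        g = gradient(_unpack(model, theta), X, Z)

        if algorithm == "gdx":
            v = hyper.momentum * self.velocity - self.lr * g
            fnew = f(theta + v)
            if not np.isfinite(fnew) or fnew > fval * hyper.max_perf_inc:
                self.lr *= hyper.lr_dec
                self.velocity = np.zeros_like(g)
                if self.lr < 1e-20:
                    return None, fval, "learning_rate_underflow"
                return theta, fval, None  # rejected step, stay put
            if fnew < fval:
                self.lr *= hyper.lr_inc
            self.velocity = v
            return theta + v, fnew, None

        if algorithm == "bfgs":
            d = self._dir_bfgs(g)
        elif algorithm == "cgp":
            d = self._dir_cgp(g, theta.size)
        elif algorithm == "oss":
            d = self._dir_oss(g, theta)
        else:
            raise ParameterError(f"unknown algorithm {algorithm!r}")

        alpha, fnew = _backtrack(f, theta, fval, g, d)
        if alpha is None:
            # retry along steepest descent before giving up
            d = -g
            alpha, fnew = _backtrack(f, theta, fval, g, d)
            if algorithm == "bfgs":
                self.H = None
            if alpha is None:
                return None, fval, "line_search"
        theta_new = theta + alpha * d
        if algorithm == "bfgs":
            g_new = gradient(_unpack(model, theta_new), X, Z)
            s = theta_new - theta
            y = g_new - g
            sy = float(s @ y)
            if sy > 1e-12:
                rho = 1.0 / sy
                I = np.eye(theta.size)
                V = I - rho * np.outer(s, y)
                self.H = V @ self.H @ V.T + rho * np.outer(s, s)
        self.g_prev = g
        self.d_prev = d
        self.theta_prev = theta
        self.iters_since_restart += 1
        return theta_new, fnew, None


def train(model: MLPModel, data: DataSplit, hyper: TrainHyper) -> TrainingReport:
    """Batch-train a model, early-stopping on validation failures.

    The returned report carries the model snapshot at the best validation
    epoch (whose validation MSE equals the minimum of the validation curve).
    """
    Zt = one_hot(data.y_train, model.sizes[-1])
    Zv = one_hot(data.y_val, model.sizes[-1])
    has_test = data.X_test is not None and data.y_test is not None
    Ztest = one_hot(data.y_test, model.sizes[-1]) if has_test else None

    theta = _pack(model)
    fval = mse(model, data.X_train, Zt)
    stopper = EarlyStopping(hyper.max_validation_failures)
    lm = _LMState(hyper)
    gs = _GradState(hyper, theta.size)

    def metrics(th: np.ndarray) -> tuple[float, float, float]:
        m = _unpack(model, th)
        return (mse(m, data.X_train, Zt), mse(m, data.X_val, Zv),
                mse(m, data.X_test, Ztest) if has_test else np.nan)

    tr, va, te = metrics(theta)
    train_curve, val_curve, test_curve = [tr], [va], [te] if has_test else []
    best_theta = theta.copy()
    stopper.update(0, va)
    best_theta = theta.copy()
    stop_reason = "max_epochs"

    for epoch in range(1, hyper.max_epochs + 1):
        if hyper.algorithm == "lm":
            theta_new, fnew, err = lm.step(model, theta, fval, data.X_train, Zt, hyper)
        else:
            theta_new, fnew, err = gs.step(hyper.algorithm, model, theta, fval,
                                           data.X_train, Zt, hyper)
        if err is not None:
            stop_reason = err
            break
        theta, fval = theta_new, fnew
        if not np.isfinite(fval):
            stop_reason = "non_finite"
            break
        tr, va, te = metrics(theta)
        train_curve.append(tr)
        val_curve.append(va)
        if has_test:
            test_curve.append(te)
        improved = va < stopper.best
        should_stop = stopper.update(epoch, va)
        if improved:
            best_theta = theta.copy()
        if tr <= hyper.goal_mse:
            stop_reason = "goal"
            break
        if should_stop:
            stop_reason = "validation"
            break

    best_model = _unpack(model, best_theta)
    report = TrainingReport(
        algorithm=hyper.algorithm, train_curve=train_curve, val_curve=val_curve,
        test_curve=test_curve, best_epoch=stopper.best_epoch,
        best_val_mse=stopper.best, stop_reason=stop_reason, model=best_model)
    report.accuracies["train"] = accuracy_percent(best_model, data.X_train, data.y_train)
    report.accuracies["val"] = accuracy_percent(best_model, data.X_val, data.y_val)
    if has_test:
        report.accuracies["test"] = accuracy_percent(best_model, data.X_test, data.y_test)
    return report


def compare_training_functions(data: DataSplit, hyper: TrainHyper,
                               seed: int,
                               algorithms: Sequence[str] = ALGORITHMS,
                               sizes: Sequence[int] = (20, 15, 5),
                               ) -> tuple[pd.DataFrame, dict[str, TrainingReport]]:
    """Train one model per algorithm from a shared initialization.

    Returns a comparison table (best validation MSE, best epoch, accuracies)
    and the full per-algorithm reports.  Deterministic for a given seed.
    """
    base = init_model(seed, sizes=sizes)
    reports: dict[str, TrainingReport] = {}
    rows = []
    for alg in algorithms:
        report = train(base.copy(), data, replace(hyper, algorithm=alg))
        reports[alg] = report
        rows.append({"algorithm": alg,
                     "label": ALGORITHM_LABELS[alg],
                     "best_val_mse": report.best_val_mse,
                     "best_epoch": report.best_epoch,
                     **{f"{k}_accuracy": v for k, v in report.accuracies.items()}})
    return pd.DataFrame(rows), reports


# ---------------------------------------------------------------------------
# serialization

def save_model(model: MLPModel, path: str | Path,
               scaler: Standardizer | None = None, meta: dict | None = None) -> None:
    """JSON serialization of the model, standardization and metadata."""
    payload = {
        "sizes": list(model.sizes),
        "activations": list(model.activations),
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "seed": model.seed,
        "standardizer": scaler.to_dict() if scaler is not None else None,
        "meta": meta or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> tuple[MLPModel, Standardizer | None, dict]:
    payload = json.loads(Path(path).read_text())
    model = MLPModel(
        tuple(payload["sizes"]),
        [np.asarray(w, dtype=float) for w in payload["weights"]],
        [np.asarray(b, dtype=float) for b in payload["biases"]],
        tuple(payload["activations"]),
        seed=payload.get("seed"))
    scaler = (Standardizer.from_dict(payload["standardizer"])
              if payload.get("standardizer") else None)
    return model, scaler, payload.get("meta", {})
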