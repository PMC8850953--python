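"""Least-squares support-vector regression (LS-SVR) with an RBF kernel.

The LS-SVM formulation replaces the epsilon-insensitive loss of classical
SVR with a squared-error loss under equality constraints, so training
reduces to one symmetric linear system instead of a quadratic program:

    [ 0   1^T          ] [ b      ]   [ 0 ]
    [ 1   K + I/gamma  ] [ lambda ] = [ y ]

where K is the kernel Gram matrix, gamma > 0 the error penalty, and the
dual coefficients lambda_i together with the bias b define the predictor
f(x) = sum_i lambda_i K(x, x_i) + b. The first block row enforces the KKT
condition sum_i lambda_i = 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.linalg

__all__ = [
    "ModelHyperparams",
    "TrainedLSSVR",
    "rbf_kernel",
    "rbf_kernel_matrix",
    "fit",
    "predict",
]

#: Linear systems with condition estimates above this are refused.
CONDITION_LIMIT = 1e12


@dataclass(frozen=True)
class ModelHyperparams:
    """Error penalty (regularisation weight) and RBF kernel width."""

    penalty: float
    kernel_width: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.penalty) and self.penalty > 0):
            raise ValueError(f"penalty must be finite and > 0, got {self.penalty}")
        if not (np.isfinite(self.kernel_width) and self.kernel_width > 0):
            raise ValueError(
                f"kernel_width must be finite and > 0, got {self.kernel_width}"
            )


def rbf_kernel(u: np.ndarray, v: np.ndarray, kernel_width: float) -> float:
    """Gaussian kernel exp(-||u - v||^2 / (2 sigma^2)), in (0, 1]."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    v = np.atleast_1d(np.asarray(v, dtype=float))
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    if kernel_width <= 0:
        raise ValueError("kernel_width must be > 0")
    return float(np.exp(-np.sum((u - v) ** 2) / (2.0 * kernel_width**2)))


def rbf_kernel_matrix(
    x1: np.ndarray, x2: np.ndarray, kernel_width: float
) -> np.ndarray:
    """Gram matrix of the RBF kernel between row sets ``x1`` and ``x2``."""
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    if x1.shape[1] != x2.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: {x1.shape[1]} vs {x2.shape[1]}"
        )
    sq = (
        np.sum(x1**2, axis=1)[:, None]
        + np.sum(x2**2, axis=1)[None, :]
        - 2.0 * x1 @ x2.T
    )
    return np.exp(-np.maximum(sq, 0.0) / (2.0 * kernel_width**2))


@dataclass
class TrainedLSSVR:
    """Fitted LS-SVR: dual coefficients, bias, hyperparameters, and the
    stored training inputs the kernel expansion is evaluated against."""

    dual_coefficients: np.ndarray
    bias: float
    hyperparams: ModelHyperparams
    train_inputs: np.ndarray
    kernel_id: str = "rbf"

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "kernel_id": self.kernel_id,
            "bias": self.bias,
            "dual_coefficients": self.dual_coefficients.tolist(),
            "train_inputs": self.train_inputs.tolist(),
            "hyperparams": {
                "penalty": self.hyperparams.penalty,
                "kernel_width": self.hyperparams.kernel_width,
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TrainedLSSVR":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            dual_coefficients=np.asarray(d["dual_coefficients"], dtype=float),
            bias=float(d["bias"]),
            hyperparams=ModelHyperparams(**d["hyperparams"]),
            train_inputs=np.asarray(d["train_inputs"], dtype=float),
            kernel_id=d["kernel_id"],
        )


def fit(x: np.ndarray, y: np.ndarray, hp: ModelHyperparams) -> TrainedLSSVR:
    """Solve the LS-SVR dual system for the given training set.

    Raises when the system's condition estimate exceeds ``CONDITION_LIMIT``
    or the solution's relative residual is above 1e-8.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = x.shape[0]
    if n < 1 or y.size != n:
        raise ValueError(f"need matching X ({n} rows) and y ({y.size} values)")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    k = rbf_kernel_matrix(x, x, hp.kernel_width)
    m = np.zeros((n + 1, n + 1))
    m[0, 1:] = 1.0
    m[1:, 0] = 1.0
    m[1:, 1:] = k + np.eye(n) / hp.penalty
    rhs = np.concatenate([[0.0], y])
    cond = np.linalg.cond(m)
    if not np.isfinite(cond) or cond > CONDITION_LIMIT:
        raise np.linalg.LinAlgError(
            f"LS-SVR dual system is ill-conditioned (condition estimate {cond:.3e})"
        )
    sol = scipy.linalg.solve(m, rhs, assume_a="sym")
    resid = np.linalg.norm(m @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if resid > 1e-8:
        raise np.linalg.LinAlgError(
            f"LS-SVR dual solve residual {resid:.3e} exceeds tolerance"
        )
    return TrainedLSSVR(
        dual_coefficients=sol[1:], bias=float(sol[0]), hyperparams=hp, train_inputs=x
    )


def predict(model: TrainedLSSVR, x_new: np.ndarray) -> np.ndarray:
    """Kernel-expansion prediction sum_i lambda_i K(x, x_i) + b per row."""
    x_new = np.atleast_2d(np.asarray(x_new, dtype=float))
    if x_new.shape[1] != model.train_inputs.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: model expects "
            f"{model.train_inputs.shape[1]}, got {x_new.shape[1]}"
        )
    k = rbf_kernel_matrix(x_new, model.train_inputs, model.hyperparams.kernel_width)
    return k @ model.dual_coefficients + model.bias
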