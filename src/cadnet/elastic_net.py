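"""Weighted elastic-net regression by cyclic coordinate descent.

The objective minimized is the un-normalized form

    L(W, b) = sum_i u_i (y_i - X_i.W - b)^2
              + lambda * (0.5 * (1 - alpha) * ||W||_2^2 + alpha * ||W||_1)

with a per-subject weight vector ``u`` (all ones by default), an unpenalized
intercept ``b``, mixing fraction ``alpha`` (1 = lasso, 0 = ridge) and
penalty strength ``lambda``.  Note there is no 1/(2n) factor: ``lambda`` is
on the scale of a raw sum of squares, so cross-checks against libraries
that normalize the loss must rescale it accordingly.

Coordinate descent uses covariance updates (the Gram matrix is formed once),
with a fixed ascending update order so runs are deterministic.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElasticNetParams",
    "TrainingData",
    "ModelWeights",
    "ConvergenceError",
    "fit",
    "predict",
    "apply_upweighting",
    "objective",
]


class ConvergenceError(RuntimeError):
    """Raised when coordinate descent does not converge within max_sweeps."""

    def __init__(self, message: str, last_objective: float):
        super().__init__(message)
        self.last_objective = last_objective


@dataclass(frozen=True)
class ElasticNetParams:
    alpha: float = 0.5
    lam: float = 1.0
    tol: float = 1e-8
    max_sweeps: int = 10_000
    standardize: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class TrainingData:
    """Design matrix, continuous target and optional per-subject weights."""

    X: np.ndarray
    y: np.ndarray
    u: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.u is None:
            self.u = np.ones(self.X.shape[0])
        else:
            self.u = np.asarray(self.u, dtype=float).ravel()
            if self.u.shape[0] != self.X.shape[0]:
                raise ValueError("u and X row counts differ")
            if np.any(self.u < 0):
                raise ValueError("weights must be nonnegative")
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.y))):
            raise ValueError("X and y must be finite (no missing values)")


@dataclass
class ModelWeights:
    """Fitted coefficients on the original feature scale.

    ``feature_index`` maps each coefficient back to its column in the
    pre-reduction feature space, so a model fitted after correlation
    filtering can be applied to the full matrix.
    """

    W: np.ndarray
    b: float
    feature_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float).ravel()
        if self.feature_index is None:
            self.feature_index = np.arange(self.W.shape[0])
        else:
            self.feature_index = np.asarray(self.feature_index, dtype=int).ravel()
        if self.feature_index.shape[0] != self.W.shape[0]:
            raise ValueError("feature_index and W lengths differ")
        if not (np.all(np.isfinite(self.W)) and np.isfinite(self.b)):
            raise ValueError("weights must be finite")

    def to_dict(self) -> dict:
        return {
            "W": self.W.tolist(),
            "b": float(self.b),
            "feature_index": self.feature_index.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelWeights":
        return cls(
            W=np.asarray(d["W"], dtype=float),
            b=float(d["b"]),
            feature_index=np.asarray(d["feature_index"], dtype=int),
        )


def objective(data: TrainingData, model: ModelWeights, params: ElasticNetParams) -> float:
    """The weighted elastic-net loss at the given coefficients."""
    r = data.y - data.X @ model.W - model.b
    penalty = params.lam * (
        0.5 * (1.0 - params.alpha) * float(model.W @ model.W)
        + params.alpha * float(np.abs(model.W).sum())
    )
    return float(data.u @ (r * r)) + penalty


def apply_upweighting(y_gensini: np.ndarray, threshold: float, factor: float) -> np.ndarray:
    """Per-subject weights: ``factor`` where the Gensini target >= threshold, else 1."""
    if factor < 1:
        raise ValueError("upweight factor must be >= 1")
    y = np.asarray(y_gensini, dtype=float)
    return np.where(y >= threshold, float(factor), 1.0)


def _soft_threshold(z: float, gamma: float) -> float:
    if z > gamma:
        return z - gamma
    if z < -gamma:
        return z + gamma
    return 0.0


def fit(data: TrainingData, params: ElasticNetParams) -> ModelWeights:
    """Minimize the weighted elastic-net loss by cyclic coordinate descent.

    Convergence: the sweep stops when the maximum per-coordinate change
    (on the fitting scale) drops below ``params.tol``.  The intercept is
    unpenalized and solved exactly from the weighted residual mean.
    Coefficients are returned on the original feature scale even when
    ``standardize`` is set.

    Raises
    ------
    ConvergenceError
        If ``max_sweeps`` full sweeps do not reach ``tol``; the exception
        carries the last objective value.
    """
    n, p = data.X.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    u = data.u

    X = data.X
    col_mean = np.zeros(p)
    col_scale = np.ones(p)
    zero_var = np.zeros(p, dtype=bool)
    if params.standardize:
        col_mean = X.mean(axis=0)
        col_scale = X.std(axis=0)
        zero_var = col_scale == 0.0
        if np.any(zero_var):
            warnings.warn(
                f"{int(zero_var.sum())} zero-variance feature(s); coefficients pinned to 0",
                RuntimeWarning,
                stacklevel=2,
            )
            col_scale = np.where(zero_var, 1.0, col_scale)
        X = (X - col_mean) / col_scale

    # Weighted centering removes the intercept from the coordinate loop:
    # at the optimum b equals the weighted mean residual.
    usum = float(u.sum())
    if usum <= 0:
        raise ValueError("weights sum to zero")
    xbar = (u @ X) / usum
    ybar = float(u @ data.y) / usum
    Xc = X - xbar
    yc = data.y - ybar

    G = Xc.T @ (u[:, None] * Xc)  # Gram matrix, p x p
    c = Xc.T @ (u * yc)
    diag = np.diag(G).copy()

    lam, alpha = params.lam, params.alpha
    l1 = lam * alpha
    denom = 2.0 * diag + lam * (1.0 - alpha)

    w = np.zeros(p)
    gw = np.zeros(p)  # G @ w, maintained incrementally
    converged = False
    for _ in range(params.max_sweeps):
        max_delta = 0.0
        for j in range(p):
            if zero_var[j] or denom[j] == 0.0:
                continue
            z = 2.0 * (c[j] - gw[j] + diag[j] * w[j])
            w_new = _soft_threshold(z, l1) / denom[j]
            dw = w_new - w[j]
            if dw != 0.0:
                gw += G[:, j] * dw
                w[j] = w_new
                max_delta = max(max_delta, abs(dw))
        if max_delta < params.tol:
            converged = True
            break

    b_fit = ybar - float(xbar @ w)
    if not converged:
        last = objective(
            TrainingData(X, data.y, u),
            ModelWeights(W=w, b=b_fit),
            params,
        )
        raise ConvergenceError(
            f"coordinate descent did not converge in {params.max_sweeps} sweeps "
            f"(last objective {last:.6g})",
            last_objective=last,
        )

    # Map back to the original feature scale.
    w_orig = w / col_scale
    w_orig[zero_var] = 0.0
    b_orig = b_fit - float(col_mean @ w_orig) if params.standardize else b_fit
    return ModelWeights(W=w_orig, b=b_orig)


def predict(model: ModelWeights, X: np.ndarray) -> np.ndarray:
    """Linear prediction ``X @ W + b``; no clipping or link function."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.W.shape[0]:
        raise ValueError(
            f"X has {X.shape[1]} columns but model expects {model.W.shape[0]}"
        )
    return X @ model.W + model.b


def save_weights(model: ModelWeights, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh)


def load_weights(path: str) -> ModelWeights:
    with open(path) as fh:
        return ModelWeights.from_dict(json.load(fh))
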