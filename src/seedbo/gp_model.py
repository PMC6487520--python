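"""Gaussian-process surrogate over scaled conditions.

The surrogate is a constant-mean GP whose covariance is a composite

    k(x_i, x_j) = alpha * C_{5/2}(||x_i - x_j|| / rho) + sigma^2 * delta_ij,

i.e. an amplitude times an isotropic Matern kernel with smoothness nu = 5/2
plus white observation noise on the diagonal.  The constant mean is pinned to
the mean of the training targets before hyperparameter fitting.  The three
hyperparameters (alpha, rho, sigma^2) are estimated by maximizing the log
marginal likelihood with a multi-start gradient search in log space; the
white-noise variance is bounded below by the germination noise floor (1/N in
global mode), and in per-observation mode the effective diagonal at point i
is max(sigma^2, floor_i).

Predictions use the standard conditional-Gaussian equations via a cached
Cholesky factorization; predictive variance excludes the observation noise
(it is the uncertainty of the latent germination response, reverting to the
prior amplitude alpha far from data).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize
from scipy.spatial.distance import cdist

from .parameter_space import ValidationError

__all__ = [
    "DEFAULT_BOUNDS",
    "JITTER",
    "KernelHyperparams",
    "GPFit",
    "GPFitError",
    "matern52",
    "kernel_eval",
    "kernel_matrix",
    "kernel_cross",
    "log_marginal_likelihood",
    "fit_mle",
]

_SQRT5 = math.sqrt(5.0)
JITTER = 1e-10
#: (amplitude, length_scale, noise-variance) boxes for the MLE search.
DEFAULT_BOUNDS = ((1e-5, 1e5), (1e-5, 1e5), (0.01, 1e5))


class GPFitError(RuntimeError):
    """All restarts of the marginal-likelihood optimization failed."""

    def __init__(self, msg: str, best_partial=None):
        super().__init__(msg)
        self.best_partial = best_partial


@dataclass(frozen=True)
class KernelHyperparams:
    """Composite-kernel hyperparameters with their optimization boxes."""

    amplitude: float
    length_scale: float
    noise: float
    amplitude_bounds: tuple[float, float] = DEFAULT_BOUNDS[0]
    length_scale_bounds: tuple[float, float] = DEFAULT_BOUNDS[1]
    noise_bounds: tuple[float, float] = DEFAULT_BOUNDS[2]

    def __post_init__(self) -> None:
        for name in ("amplitude", "length_scale", "noise"):
            v = getattr(self, name)
            lo, hi = getattr(self, f"{name}_bounds")
            if not (v > 0 and np.isfinite(v)):
                raise ValidationError(f"{name} must be positive and finite, got {v}")
            if not (lo * (1 - 1e-9) <= v <= hi * (1 + 1e-9)):
                raise ValidationError(f"{name}={v} outside bounds [{lo}, {hi}]")

    @property
    def bounds(self) -> tuple[tuple[float, float], ...]:
        return (self.amplitude_bounds, self.length_scale_bounds, self.noise_bounds)


def matern52(r):
    """Matern correlation with nu = 5/2 at scaled distance r = ||a - b|| / rho."""
    t = _SQRT5 * np.asarray(r, dtype=float)
    return (1.0 + t + t * t / 3.0) * np.exp(-t)


def kernel_eval(a: Sequence[float], b: Sequence[float], h: KernelHyperparams,
                same_index: bool = False) -> float:
    """Covariance between two points; white noise applies only when the two
    arguments are the same *training index* (``same_index=True``)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValidationError(f"dimension mismatch: {a.shape} vs {b.shape}")
    r = np.linalg.norm(a - b) / h.length_scale
    k = h.amplitude * matern52(r)
    if same_index:
        k += h.noise
    return float(k)


def kernel_cross(Xa: np.ndarray, Xb: np.ndarray, h: KernelHyperparams) -> np.ndarray:
    """Noise-free cross-covariance matrix between two point sets."""
    Xa = np.atleast_2d(np.asarray(Xa, float))
    Xb = np.atleast_2d(np.asarray(Xb, float))
    if Xa.shape[1] != Xb.shape[1]:
        raise ValidationError("dimension mismatch between point sets")
    return h.amplitude * matern52(cdist(Xa, Xb) / h.length_scale)


def _diag_noise(h: KernelHyperparams, n: int, floors: Optional[np.ndarray]) -> np.ndarray:
    if floors is None:
        return np.full(n, h.noise)
    return np.maximum(h.noise, floors)


def kernel_matrix(X: np.ndarray, h: KernelHyperparams,
                  floors: Optional[np.ndarray] = None) -> np.ndarray:
    """Regularized training covariance alpha*C + diag(max(sigma^2, floor)) + jitter."""
    K = kernel_cross(X, X, h)
    K[np.diag_indices_from(K)] += _diag_noise(h, K.shape[0], floors) + JITTER
    return K


def log_marginal_likelihood(h: KernelHyperparams, X: np.ndarray, y: np.ndarray,
                            mean: float, floors: Optional[np.ndarray] = None) -> float:
    """Gaussian log marginal likelihood of (y - mean) under the kernel."""
    K = kernel_matrix(X, h, floors)
    r = np.asarray(y, float) - mean
    try:
        c, low = cho_factor(K, lower=True)
    except np.linalg.LinAlgError:
        return -np.inf
    alpha = cho_solve((c, low), r)
    return float(-0.5 * r @ alpha - np.sum(np.log(np.diag(c))) - 0.5 * len(r) * math.log(2 * math.pi))


class GPFit:
    """A fitted GP: hyperparameters, fixed constant mean, cached factorization.

    Instances are treated as immutable; :meth:`with_observation` returns a new
    fit sharing hyperparameters and mean, which is how fantasy points are
    added during batch suggestion without touching the original state.
    """

    def __init__(self, hyperparams: KernelHyperparams, mean: float,
                 X: np.ndarray, y: np.ndarray,
                 floors: Optional[np.ndarray] = None):
        self.hyperparams = hyperparams
        self.mean = float(mean)
        self.X = np.atleast_2d(np.asarray(X, float)).copy()
        self.y = np.asarray(y, float).copy()
        self.floors = None if floors is None else np.asarray(floors, float).copy()
        if self.X.shape[0] != self.y.shape[0]:
            raise ValidationError("X and y row counts differ")
        if self.floors is not None and self.floors.shape[0] != self.y.shape[0]:
            raise ValidationError("floors length differs from y")
        K = kernel_matrix(self.X, hyperparams, self.floors)
        self._L = np.linalg.cholesky(K)
        self._alpha = cho_solve((self._L, True), self.y - self.mean)
        self.log_marginal_likelihood = float(
            -0.5 * (self.y - self.mean) @ self._alpha
            - np.sum(np.log(np.diag(self._L)))
            - 0.5 * len(self.y) * math.log(2 * math.pi)
        )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    @property
    def incumbent(self) -> np.ndarray:
        """Training input with the highest observed target."""
        return self.X[int(np.argmax(self.y))]

    def predict(self, Xq) -> tuple[np.ndarray, np.ndarray]:
        """Predictive mean and standard deviation of the latent response.

        mean(x*) = m + k*^T (K + D)^-1 (y - m)
        var(x*)  = k(x*, x*) - k*^T (K + D)^-1 k*, clipped at 0.
        """
        Xq = np.atleast_2d(np.asarray(Xq, float))
        if Xq.shape[1] != self.dim:
            raise ValidationError(f"query dim {Xq.shape[1]} != training dim {self.dim}")
        Ks = kernel_cross(Xq, self.X, self.hyperparams)
        mu = self.mean + Ks @ self._alpha
        v = solve_triangular(self._L, Ks.T, lower=True)
        var = np.clip(self.hyperparams.amplitude - np.sum(v * v, axis=0), 0.0, None)
        return mu, np.sqrt(var)

    def predict_one(self, x) -> tuple[float, float]:
        mu, sd = self.predict(np.atleast_2d(x))
        return float(mu[0]), float(sd[0])

    def with_observation(self, x, y: float, floor: Optional[float] = None) -> "GPFit":
        """New fit with one extra point, same hyperparameters and mean (no refit)."""
        Xn = np.vstack([self.X, np.atleast_2d(np.asarray(x, float))])
        yn = np.append(self.y, float(y))
        if self.floors is None:
            fn = None
        else:
            fn = np.append(self.floors, self.floors.max() if floor is None else float(floor))
        return GPFit(self.hyperparams, self.mean, Xn, yn, fn)

    # -- light persistence (training data lives in the ledger CSV) ----------

    def to_json(self, path=None) -> str:
        doc = {
            "amplitude": self.hyperparams.amplitude,
            "length_scale": self.hyperparams.length_scale,
            "noise": self.hyperparams.noise,
            "bounds": [list(b) for b in self.hyperparams.bounds],
            "mean": self.mean,
            "log_marginal_likelihood": self.log_marginal_likelihood,
        }
        s = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(s)
        return s

    @staticmethod
    def hyperparams_from_json(s: str) -> KernelHyperparams:
        doc = json.loads(s)
        b = doc["bounds"]
        return KernelHyperparams(doc["amplitude"], doc["length_scale"], doc["noise"],
                                 tuple(b[0]), tuple(b[1]), tuple(b[2]))


def fit_mle(
    X,
    y,
    *,
    floors=None,
    bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS,
    n_restarts: int = 30,
    rng: Optional[np.random.Generator] = None,
    mean: Optional[float] = None,
) -> GPFit:
    """Fit hyperparameters by maximum marginal likelihood with restarts.

    The search runs L-BFGS-B on the negative log marginal likelihood in
    log-hyperparameter space from ``n_restarts`` starting points: one
    moderate default (amplitude = target variance, unit length scale, noise
    at its lower bound) and the rest log-uniform over the bounds boxes.
    The constant mean is fixed to ``mean(y)`` before fitting.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    if X.shape[0] < 2:
        raise ValidationError("need at least 2 observations to fit")
    if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
        raise ValidationError("non-finite training data")
    if floors is not None:
        floors = np.asarray(floors, float)
        if floors.shape[0] != y.shape[0]:
            raise ValidationError("floors length differs from y")
    rng = np.random.default_rng(rng)
    bounds = tuple((float(lo), float(hi)) for lo, hi in bounds)
    m = float(np.mean(y)) if mean is None else float(mean)
    log_bounds = [(math.log(lo), math.log(hi)) for lo, hi in bounds]

    def nll(theta: np.ndarray) -> float:
        h = KernelHyperparams(*np.exp(theta), *bounds)
        ll = log_marginal_likelihood(h, X, y, m, floors)
        return 1e25 if not np.isfinite(ll) else -ll

    def clip_log(vals):
        return [min(max(math.log(v), lo), hi) for v, (lo, hi) in zip(vals, log_bounds)]

    yvar = float(np.var(y))
    starts = [clip_log([yvar if yvar > 0 else 1.0, 1.0, bounds[2][0]])]
    for _ in range(max(0, n_restarts - 1)):
        starts.append([rng.uniform(lo, hi) for lo, hi in log_bounds])

    best = None
    for s in starts:
        res = minimize(nll, np.asarray(s), method="L-BFGS-B", bounds=log_bounds)
        if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e25:
        raise GPFitError("all marginal-likelihood restarts failed", best_partial=best)
    a, r, s2 = np.exp(np.clip(best.x, [b[0] for b in log_bounds], [b[1] for b in log_bounds]))
    h = KernelHyperparams(a, r, s2, *bounds)
    return GPFit(h, m, X, y, floors)
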