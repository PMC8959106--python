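"""Exact Gaussian process regression with a squared-exponential kernel.

Implements the standard zero-mean GP machinery: kernel evaluation,
Cholesky-based log marginal likelihood with analytic gradients,
multi-start bounded hyperparameter optimization, and the exact posterior
predictive mean/variance.  Targets are centred by their training mean so
that far from the data the posterior reverts to the cohort average rather
than to zero — the behaviour wanted when the model falls back to a
population-mean gait for an out-of-range subject.

The kernel is

    k(x, x') = sigma_f^2 * exp(-1/2 * sum_d (x_d - x'_d)^2 / l_d^2)

with either a shared (isotropic) lengthscale or one per input dimension
(ARD), plus i.i.d. Gaussian observation noise sigma_n^2.  Hyperparameters
are fitted by maximizing the log marginal likelihood in log-space with
L-BFGS-B, bounds three decades either side of the data scales, and a
configurable number of random restarts.
"""
from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

JITTER_START = 1e-10
JITTER_MAX = 1e-4


class GPNumericalError(RuntimeError):
    """Raised when the kernel matrix cannot be factorized or fitting fails."""


@dataclass
class KernelConfig:
    """Squared-exponential kernel + noise hyperparameters and fit settings.

    ``bounds_decades`` sets the multiplicative search range around the data
    scales (default 1e3 each way); ``n_restarts`` counts total optimizer
    starts (the first is a data-driven heuristic, the rest random).
    """

    signal_variance: float = 1.0
    lengthscale: float | np.ndarray = 1.0
    noise_variance: float = 0.01
    ard: bool = False
    n_restarts: int = 5
    bounds_decades: float = 1e3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.signal_variance <= 0:
            raise ValueError("signal_variance must be > 0")
        if np.any(np.asarray(self.lengthscale) <= 0):
            raise ValueError("lengthscale must be > 0 elementwise")
        if self.noise_variance < 0:
            raise ValueError("noise_variance must be >= 0")

    def lengthscale_vector(self, ndim: int) -> np.ndarray:
        ell = np.asarray(self.lengthscale, dtype=float)
        if ell.ndim == 0:
            return np.full(max(ndim, 1), float(ell))
        if ell.shape != (ndim,):
            raise ValueError(f"lengthscale shape {ell.shape} does not match ndim {ndim}")
        return ell


def _as_2d(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("inputs must be 2-D (n_points, n_dims)")
    return X


def _scaled_sq_dists(X1: np.ndarray, X2: np.ndarray, ell: np.ndarray) -> np.ndarray:
    """Pairwise sum_d (x1_d - x2_d)^2 / l_d^2; zero matrix for 0-dim inputs."""
    if X1.shape[1] == 0:
        return np.zeros((X1.shape[0], X2.shape[0]))
    A = X1 / ell
    B = X2 / ell
    d2 = (
        np.sum(A * A, axis=1)[:, None]
        + np.sum(B * B, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return np.maximum(d2, 0.0)


def kernel_matrix(X1: np.ndarray, X2: np.ndarray, config: KernelConfig) -> np.ndarray:
    """Cross-covariance matrix K[i, j] = k(x1_i, x2_j) (no noise term)."""
    X1, X2 = _as_2d(X1), _as_2d(X2)
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(f"input dimension mismatch: {X1.shape[1]} vs {X2.shape[1]}")
    d = X1.shape[1]
    if d == 0:
        d2 = np.zeros((X1.shape[0], X2.shape[0]))
    else:
        d2 = _scaled_sq_dists(X1, X2, config.lengthscale_vector(d))
    return config.signal_variance * np.exp(-0.5 * d2)


def _chol_with_jitter(K: np.ndarray, noise_variance: float) -> tuple[np.ndarray, float]:
    """Lower Cholesky factor of K + (noise + jitter) I, escalating jitter."""
    m = K.shape[0]
    jitter = JITTER_START
    while jitter <= JITTER_MAX:
        try:
            L = cholesky(K + (noise_variance + jitter) * np.eye(m), lower=True)
            return L, jitter
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise GPNumericalError(
        f"kernel matrix not positive definite even with jitter {JITTER_MAX:g} "
        f"(m={m}, noise_variance={noise_variance:g})"
    )


def log_marginal_likelihood(X: np.ndarray, y: np.ndarray, config: KernelConfig) -> float:
    """Log evidence of centred targets ``y`` under the GP prior + noise."""
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y have different numbers of points")
    if y.size < 1:
        raise ValueError("need at least one training point")
    K = kernel_matrix(X, X, config)
    L, _ = _chol_with_jitter(K, config.noise_variance)
    alpha = cho_solve((L, True), y)
    return float(
        -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * y.size * np.log(2.0 * np.pi)
    )


def _lml_and_grad(
    theta: np.ndarray, X: np.ndarray, y: np.ndarray, ard: bool
) -> tuple[float, np.ndarray]:
    """Negative log marginal likelihood and gradient in log-hyperparameters.

    theta = [log sigma_f, log l_1..l_d (or log l), log sigma_n].
    """
    m, d = X.shape
    n_ell = d if ard else 1
    sf2 = np.exp(2.0 * theta[0])
    ell = np.exp(theta[1 : 1 + n_ell])
    sn2 = np.exp(2.0 * theta[-1])
    ell_full = ell if ard else np.full(max(d, 1), ell[0])

    if d:
        diff = X[:, None, :] - X[None, :, :]  # (m, m, d)
        sq = (diff / ell_full) ** 2
        d2 = sq.sum(axis=2)
    else:
        sq = np.zeros((m, m, 0))
        d2 = np.zeros((m, m))
    K = sf2 * np.exp(-0.5 * d2)
    L, jitter = _chol_with_jitter(K, sn2)
    alpha = cho_solve((L, True), y)
    lml = -0.5 * y @ alpha - np.sum(np.log(np.diag(L))) - 0.5 * m * np.log(2.0 * np.pi)

    Kinv = cho_solve((L, True), np.eye(m))
    W = np.outer(alpha, alpha) - Kinv  # d lml / dK = W / 2

    grad = np.empty_like(theta)
    grad[0] = 0.5 * np.sum(W * (2.0 * K))
    if ard:
        for j in range(d):
            grad[1 + j] = 0.5 * np.sum(W * (K * sq[:, :, j]))
    else:
        grad[1] = 0.5 * np.sum(W * (K * d2))
    grad[-1] = 0.5 * np.trace(W) * 2.0 * sn2
    return -float(lml), -grad


@dataclass
class GPRModel:
    """A fitted GP: training data, hyperparameters and cached factorization."""

    X: np.ndarray
    y: np.ndarray
    y_mean: float
    config: KernelConfig
    degenerate: bool = False  # constant targets: predict the mean exactly
    _L: np.ndarray | None = None
    _alpha: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.degenerate and self._L is None:
            K = kernel_matrix(self.X, self.X, self.config)
            L, _ = _chol_with_jitter(K, self.config.noise_variance)
            self._L = L
            self._alpha = cho_solve((L, True), self.y - self.y_mean)

    @property
    def n_train(self) -> int:
        return self.X.shape[0]


def _heuristic_start(X: np.ndarray, y_scale: float, ard: bool) -> tuple[np.ndarray, float]:
    """Data-driven initial lengthscale: median pairwise distance of the inputs."""
    m, d = X.shape
    if d == 0 or m < 2:
        return np.ones(d if ard else 1), y_scale
    diffs = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diffs**2).sum(axis=2))
    pos = dist[np.triu_indices(m, k=1)]
    pos = pos[pos > 0]
    base = float(np.median(pos)) if pos.size else 1.0
    if ard:
        col_scale = X.std(axis=0)
        col_scale = np.where(col_scale > 0, col_scale, 1.0)
        ell0 = col_scale * base / max(np.mean(col_scale), 1e-300)
    else:
        ell0 = np.array([base])
    return ell0, y_scale


def fit(
    X: np.ndarray,
    y: np.ndarray,
    config: KernelConfig | None = None,
    optimize: bool = True,
) -> GPRModel:
    """Fit a GP to (X, y), optionally optimizing hyperparameters.

    Targets are centred by their mean internally.  With ``optimize=False``
    (or fewer than two points) the hyperparameters in ``config`` are used
    as-is.  Numerically constant targets short-circuit to a degenerate
    model that predicts the constant with zero variance.
    """
    config = config or KernelConfig()
    X = _as_2d(X)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size or y.size < 1:
        raise ValueError("X and y must be non-empty and aligned")
    y_mean = float(y.mean())
    yc = y - y_mean
    y_scale = float(yc.std())

    if y_scale <= 1e-12 * (1.0 + abs(y_mean)):
        return GPRModel(X=X, y=y, y_mean=y_mean, config=config, degenerate=True)

    if not optimize or X.shape[0] < 2:
        return GPRModel(X=X, y=y, y_mean=y_mean, config=config)

    m, d = X.shape
    ard = config.ard
    n_ell = d if ard else 1
    ell0, sf0 = _heuristic_start(X, y_scale, ard)
    dec = np.log(config.bounds_decades)
    bounds_lo = np.concatenate(
        [[np.log(y_scale) - dec], np.log(ell0) - dec, [np.log(y_scale) - dec]]
    )
    bounds_hi = np.concatenate(
        [[np.log(y_scale) + dec], np.log(ell0) + dec, [np.log(y_scale) + dec]]
    )
    theta0 = np.concatenate(
        [[np.log(y_scale)], np.log(ell0), [np.log(0.1 * y_scale)]]
    )
    theta0 = np.clip(theta0, bounds_lo, bounds_hi)

    rng = np.random.default_rng(config.seed)
    starts = [theta0]
    for _ in range(max(config.n_restarts - 1, 0)):
        starts.append(rng.uniform(bounds_lo, bounds_hi))

    best = None
    failures: list[str] = []
    for start in starts:
        try:
            res = minimize(
                _lml_and_grad,
                start,
                args=(X, yc, ard),
                jac=True,
                method="L-BFGS-B",
                bounds=list(zip(bounds_lo, bounds_hi)),
            )
        except GPNumericalError as exc:
            failures.append(str(exc))
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise GPNumericalError(
            "all hyperparameter optimization restarts failed: " + "; ".join(failures)
        )

    theta = best.x
    fitted = replace(
        config,
        signal_variance=float(np.exp(2.0 * theta[0])),
        lengthscale=(
            np.exp(theta[1 : 1 + n_ell]) if ard else float(np.exp(theta[1]))
        ),
        noise_variance=float(np.exp(2.0 * theta[-1])),
    )
    return GPRModel(X=X, y=y, y_mean=y_mean, config=fitted)


def predict(model: GPRModel, Xq: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact posterior mean and (latent, noise-free) variance at the queries."""
    Xq = _as_2d(Xq)
    if Xq.shape[1] != model.X.shape[1]:
        raise ValueError(
            f"query dimension {Xq.shape[1]} does not match training {model.X.shape[1]}"
        )
    nq = Xq.shape[0]
    if model.degenerate:
        return np.full(nq, model.y_mean), np.zeros(nq)
    Ks = kernel_matrix(Xq, model.X, model.config)
    mean = Ks @ model._alpha + model.y_mean
    v = solve_triangular(model._L, Ks.T, lower=True)
    var = model.config.signal_variance - np.sum(v * v, axis=0)
    return mean, np.maximum(var, 0.0)


def model_to_dict(model: GPRModel) -> dict:
    """JSON-serializable representation (exact float round-trip)."""
    cfg = model.config
    ell = cfg.lengthscale
    return {
        "X": model.X.tolist(),
        "y": model.y.tolist(),
        "y_mean": model.y_mean,
        "degenerate": model.degenerate,
        "kernel": {
            "signal_variance": cfg.signal_variance,
            "lengthscale": ell.tolist() if isinstance(ell, np.ndarray) else ell,
            "noise_variance": cfg.noise_variance,
            "ard": cfg.ard,
        },
    }


def model_from_dict(payload: dict) -> GPRModel:
    k = payload["kernel"]
    ell = k["lengthscale"]
    config = KernelConfig(
        signal_variance=k["signal_variance"],
        lengthscale=np.asarray(ell, dtype=float) if isinstance(ell, list) else float(ell),
        noise_variance=k["noise_variance"],
        ard=k["ard"],
    )
    return GPRModel(
        X=np.asarray(payload["X"], dtype=float),
        y=np.asarray(payload["y"], dtype=float),
        y_mean=float(payload["y_mean"]),
        config=config,
        degenerate=bool(payload["degenerate"]),
    )
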