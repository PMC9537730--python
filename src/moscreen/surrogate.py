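"""Exact Gaussian-process regression surrogate, one model per objective.

The surrogate places a GP prior f ~ N(mu_0, K) over the transformed
objective as a function of the embedding coordinates and conditions on the
molecules evaluated so far. With K the kernel matrix of the training inputs
(noise variance on the diagonal) and k_* the cross-covariances to a query
point, the posterior is

    mu_n(x)     = k_*^T K^{-1} (y - mu_0) + mu_0
    sigma_n2(x) = k(x, x) + noise - k_*^T K^{-1} k_*

All solves go through a cached Cholesky factor of K (triangular solves,
never an explicit inverse). Targets are standardized to zero mean / unit
variance before fitting and predictions are de-standardized, so objectives
with wildly different raw scales (kcal/mol vs unit-height scores) optimize
identically. Hyperparameters maximize the log marginal likelihood via
L-BFGS with analytic gradients from a deterministic, data-driven start.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist

logger = logging.getLogger("moscreen")

#: jitter escalation ladder added to the covariance diagonal until the
#: Cholesky succeeds; exceeding the last rung is an error
_JITTERS = (0.0, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3)

#: floor on the learned noise variance (standardized target scale)
_NOISE_FLOOR = 1e-8


@dataclass(frozen=True)
class KernelSpec:
    """Stationary kernel family plus its (learned) scale parameters.

    ``lengthscale`` is shared across embedding dimensions; ``signal_variance``
    and ``noise_variance`` are on the standardized-target scale.
    """

    family: str = "rbf"
    lengthscale: float = 1.0
    signal_variance: float = 1.0
    noise_variance: float = 1e-2

    def __post_init__(self) -> None:
        if self.family not in ("rbf", "matern52"):
            raise ValueError(f"unknown kernel family {self.family!r}")
        for name in ("lengthscale", "signal_variance", "noise_variance"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class GPModel:
    """A fitted surrogate: training data, kernel, and cached Cholesky factor.

    ``train_y`` is stored standardized; ``y_loc``/``y_scale`` de-standardize
    predictions. ``mean_const`` is the constant prior mean on the
    standardized scale (0 by construction).
    """

    train_x: np.ndarray
    train_y: np.ndarray
    kernel: KernelSpec
    mean_const: float
    cholesky_factor: np.ndarray
    alpha: np.ndarray  # K^{-1} (y - mean_const), cached
    y_loc: float
    y_scale: float
    jitter: float


@dataclass(frozen=True)
class PosteriorPrediction:
    """Posterior mean and variance per query molecule, de-standardized."""

    mean: np.ndarray
    variance: np.ndarray


def kernel_matrix(spec: KernelSpec, x: np.ndarray,
                  z: np.ndarray | None = None) -> np.ndarray:
    """Signal covariance between rows of ``x`` and ``z`` (noise excluded)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    z = x if z is None else np.atleast_2d(np.asarray(z, dtype=float))
    r = cdist(x, z)
    if spec.family == "rbf":
        base = np.exp(-0.5 * (r / spec.lengthscale) ** 2)
    else:  # matern52
        a = math.sqrt(5.0) * r / spec.lengthscale
        base = (1.0 + a + a * a / 3.0) * np.exp(-a)
    return spec.signal_variance * base


def _jittered_cholesky(k_train: np.ndarray) -> tuple[np.ndarray, float]:
    n = k_train.shape[0]
    for jitter in _JITTERS:
        try:
            lower = cholesky(k_train + jitter * np.eye(n), lower=True)
        except np.linalg.LinAlgError:
            continue
        if jitter > 0:
            logger.warning("covariance needed jitter %g for Cholesky", jitter)
        return lower, jitter
    raise np.linalg.LinAlgError(
        "covariance not positive-definite even at maximum jitter 1e-3"
    )


def log_marginal_likelihood(x: np.ndarray, y: np.ndarray,
                            spec: KernelSpec) -> float:
    """Exact GP log marginal likelihood of (standardized) targets ``y``."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    k_train = kernel_matrix(spec, x) + spec.noise_variance * np.eye(n)
    lower, _ = _jittered_cholesky(k_train)
    alpha = cho_solve((lower, True), y)
    return float(
        -0.5 * y @ alpha
        - np.log(np.diag(lower)).sum()
        - 0.5 * n * math.log(2.0 * math.pi)
    )


def _nll_and_grad(theta: np.ndarray, x: np.ndarray, y: np.ndarray,
                  family: str) -> tuple[float, np.ndarray]:
    """Negative LML and gradient w.r.t. (log ls, log signal, log noise)."""
    ls, sig, noise = np.exp(theta)
    n = y.shape[0]
    r = cdist(x, x)
    if family == "rbf":
        q = (r / ls) ** 2
        base = np.exp(-0.5 * q)
        dk_dlogls = sig * base * q
    else:
        a = math.sqrt(5.0) * r / ls
        expa = np.exp(-a)
        base = (1.0 + a + a * a / 3.0) * expa
        dk_dlogls = sig * expa * a * a * (1.0 + a) / 3.0
    k_signal = sig * base
    k_train = k_signal + noise * np.eye(n)
    try:
        lower, _ = _jittered_cholesky(k_train)
    except np.linalg.LinAlgError:
        return 1e25, np.zeros(3)
    alpha = cho_solve((lower, True), y)
    nll = (0.5 * y @ alpha + np.log(np.diag(lower)).sum()
           + 0.5 * n * math.log(2.0 * math.pi))
    # dNLL/dtheta_j = 0.5 tr((K^{-1} - alpha alpha^T) dK/dtheta_j)
    k_inv = cho_solve((lower, True), np.eye(n))
    w = k_inv - np.outer(alpha, alpha)
    grad = np.array([
        0.5 * np.sum(w * dk_dlogls),
        0.5 * np.sum(w * k_signal),
        0.5 * noise * np.trace(w),
    ])
    return float(nll), grad


def initial_kernel(train_x: np.ndarray, kernel_family: str = "rbf") -> KernelSpec:
    """Deterministic data-driven start: median pairwise distance lengthscale,
    unit signal variance, 1e-2 noise variance (standardized scale)."""
    train_x = np.atleast_2d(np.asarray(train_x, dtype=float))
    dists = pdist(train_x)
    dists = dists[dists > 0]
    ls = float(np.median(dists)) if dists.size else 1.0
    return KernelSpec(kernel_family, ls, 1.0, 1e-2)


def fit_gp(train_x: np.ndarray, train_y: np.ndarray,
           kernel_family: str = "rbf", seed: int = 0,
           max_iter: int = 200, optimize: bool = True,
           kernel: KernelSpec | None = None) -> GPModel:
    """Fit the surrogate on the evaluated molecules.

    Targets are standardized internally (degenerate zero-variance targets
    keep scale 1). Hyperparameters maximize the log marginal likelihood with
    L-BFGS from the :func:`initial_kernel` start; the fit is deterministic —
    ``seed`` is part of the contract for surrogates with stochastic training
    but unused by the exact GP. Pass ``kernel`` with ``optimize=False`` to
    pin hyperparameters.
    """
    train_x = np.atleast_2d(np.asarray(train_x, dtype=float))
    train_y = np.asarray(train_y, dtype=float)
    if train_y.ndim != 1 or train_x.shape[0] != train_y.shape[0]:
        raise ValueError("train_x rows must match train_y length")
    if train_y.shape[0] < 2:
        raise ValueError("need at least 2 training points")
    if not (np.all(np.isfinite(train_x)) and np.all(np.isfinite(train_y))):
        raise ValueError("non-finite training data")

    y_loc = float(train_y.mean())
    y_scale = float(train_y.std())
    if y_scale == 0.0:
        y_scale = 1.0
    y_std = (train_y - y_loc) / y_scale

    spec = kernel if kernel is not None else initial_kernel(train_x, kernel_family)
    if optimize:
        ls0 = spec.lengthscale
        theta0 = np.log([spec.lengthscale, spec.signal_variance,
                         spec.noise_variance])
        bounds = [
            (math.log(ls0 * 1e-3), math.log(ls0 * 1e3)),
            (math.log(1e-4), math.log(1e4)),
            (math.log(_NOISE_FLOOR), math.log(10.0)),
        ]
        res = minimize(_nll_and_grad, theta0,
                       args=(train_x, y_std, spec.family),
                       jac=True, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": max_iter})
        ls, sig, noise = np.exp(res.x)
        spec = replace(spec, lengthscale=float(ls),
                       signal_variance=float(sig),
                       noise_variance=float(max(noise, _NOISE_FLOOR)))

    n = train_y.shape[0]
    k_train = kernel_matrix(spec, train_x) + spec.noise_variance * np.eye(n)
    lower, jitter = _jittered_cholesky(k_train)
    alpha = cho_solve((lower, True), y_std)
    return GPModel(train_x=train_x, train_y=y_std, kernel=spec,
                   mean_const=0.0, cholesky_factor=lower, alpha=alpha,
                   y_loc=y_loc, y_scale=y_scale, jitter=jitter)


def predict(model: GPModel, query_x: np.ndarray,
            chunk_size: int | None = None) -> PosteriorPrediction:
    """Posterior mean and predictive variance over query molecules.

    Computed with triangular solves against the cached Cholesky factor.
    The variance is the predictive (observation) variance: it includes the
    noise term, so far from the data it reverts to signal + noise, and at a
    training input it collapses to the noise floor. ``chunk_size`` bounds
    memory on very large pools without changing results.
    """
    query_x = np.atleast_2d(np.asarray(query_x, dtype=float))
    if query_x.shape[1] != model.train_x.shape[1]:
        raise ValueError(
            f"query dimension {query_x.shape[1]} != training dimension "
            f"{model.train_x.shape[1]}"
        )
    spec = model.kernel
    n_query = query_x.shape[0]
    mean = np.empty(n_query)
    var = np.empty(n_query)
    step = chunk_size or n_query
    prior_var = spec.signal_variance + spec.noise_variance
    for start in range(0, n_query, max(step, 1)):
        sl = slice(start, min(start + step, n_query))
        k_star = kernel_matrix(spec, model.train_x, query_x[sl])  # n x q
        mean[sl] = k_star.T @ model.alpha + model.mean_const
        v = solve_triangular(model.cholesky_factor, k_star, lower=True)
        var[sl] = prior_var - np.einsum("ij,ij->j", v, v)
    np.clip(var, 0.0, None, out=var)
    return PosteriorPrediction(
        mean=model.y_loc + model.y_scale * mean,
        variance=model.y_scale**2 * var,
    )
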