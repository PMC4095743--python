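"""Kernel regressors for strength prediction.

Both regressors use the Laplacian kernel K(x, y) = exp(-sigma * ||x - y||)
with the Euclidean norm.

* Support vector regression with epsilon-insensitive loss is solved through
  libsvm (scikit-learn) on a precomputed Gram matrix; the fitted model keeps
  only the support vectors and their dual coefficients.
* The relevance vector machine is implemented here directly: Bayesian linear
  regression over the kernel basis (one basis function per training point
  plus a constant bias), with an independent Gaussian prior N(0, 1/alpha_i)
  on each weight. Hyperparameters are fit by evidence maximisation; as the
  iteration proceeds most alpha_i diverge and their basis functions are
  pruned, leaving a sparse set of relevance vectors. beta denotes the noise
  precision (the Gaussian likelihood has variance 1/beta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.svm import SVR as _SkSVR

__all__ = [
    "KernelSpec",
    "laplacian_kernel",
    "laplacian_gram",
    "SVRModel",
    "RVMModel",
    "svr_fit",
    "rvm_fit",
    "predict",
]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameter; only the Laplacian kernel is supported."""

    sigma: float
    name: str = "laplacian"

    def __post_init__(self) -> None:
        if self.name != "laplacian":
            raise ValueError(f"unsupported kernel {self.name!r}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")


def laplacian_kernel(x, y, sigma: float) -> float:
    """exp(-sigma * ||x - y||_2); symmetric, K(x, x) = 1, range (0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return float(np.exp(-sigma * np.linalg.norm(x - y)))


def laplacian_gram(X, Y, sigma: float) -> np.ndarray:
    """Pairwise Laplacian kernel matrix between the rows of X and Y."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    return np.exp(-sigma * euclidean_distances(X, Y))


# ---------------------------------------------------------------------------
# SVR
# ---------------------------------------------------------------------------

@dataclass
class SVRModel:
    """Fitted epsilon-insensitive SVR in dual form.

    ``dual_coefficients`` are alpha_i - alpha_i* for the support vectors,
    each bounded by C in absolute value.
    """

    support_vectors: np.ndarray
    dual_coefficients: np.ndarray
    bias: float
    C: float
    epsilon: float
    kernel: KernelSpec

    @property
    def n_support(self) -> int:
        """Support-vector count: dual coefficients above 1e-8 in magnitude."""
        return int(np.sum(np.abs(self.dual_coefficients) > 1e-8))

    def predict(self, X_new, clip: bool = False) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if self.support_vectors.shape[0] == 0:
            out = np.full(X_new.shape[0], self.bias)
        else:
            K = laplacian_gram(X_new, self.support_vectors, self.kernel.sigma)
            out = K @ self.dual_coefficients + self.bias
        return np.clip(out, 0.0, 1.0) if clip else out


def svr_fit(
    X,
    y,
    C: float,
    epsilon: float,
    kernel: KernelSpec,
    tol: float = 1e-6,
) -> SVRModel:
    """Fit epsilon-insensitive SVR with the Laplacian kernel.

    The dual quadratic program is solved by libsvm on the precomputed Gram
    matrix to tolerance ``tol``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("SVR needs at least two training points")
    if C <= 0 or epsilon < 0:
        raise ValueError("require C > 0 and epsilon >= 0")
    K = laplacian_gram(X, X, kernel.sigma)
    est = _SkSVR(kernel="precomputed", C=C, epsilon=epsilon, tol=tol, max_iter=-1)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=ConvergenceWarning)
        try:
            est.fit(K, y)
        except ConvergenceWarning as w:
            raise RuntimeError(f"SVR solver did not converge: {w}") from None
    return SVRModel(
        support_vectors=X[est.support_],
        dual_coefficients=est.dual_coef_[0].copy(),
        bias=float(est.intercept_[0]),
        C=C,
        epsilon=epsilon,
        kernel=kernel,
    )


# ---------------------------------------------------------------------------
# RVM
# ---------------------------------------------------------------------------

@dataclass
class RVMModel:
    """Fitted relevance vector machine over the Laplacian kernel basis.

    ``weights`` and ``alpha`` are aligned with the retained basis functions:
    the constant bias first when ``bias_included``, then one kernel basis per
    relevance vector.
    """

    relevance_vectors: np.ndarray
    weights: np.ndarray
    alpha: np.ndarray
    beta: float
    bias_included: bool
    kernel: KernelSpec
    evidence_history: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def n_relevance(self) -> int:
        """Relevance-vector count (kernel bases retained after pruning)."""
        return int(self.relevance_vectors.shape[0])

    def predict(self, X_new, clip: bool = False) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        cols = []
        if self.bias_included:
            cols.append(np.ones((X_new.shape[0], 1)))
        if self.n_relevance:
            cols.append(laplacian_gram(X_new, self.relevance_vectors, self.kernel.sigma))
        Phi = np.hstack(cols)
        out = Phi @ self.weights
        return np.clip(out, 0.0, 1.0) if clip else out


def _posterior(PTP, PTy, alpha, beta):
    """Posterior of the weights given fixed hyperparameters.

    Works from the precomputed Gram cross-products Phi'Phi and Phi'y.
    Returns (Sigma, mu, logdet_precision); adds escalating diagonal jitter
    if the precision matrix cannot be factorised.
    """
    H = beta * PTP + np.diag(alpha)
    jitter = 0.0
    for attempt in range(8):
        try:
            chol = scipy.linalg.cho_factor(H + jitter * np.eye(H.shape[0]), lower=True)
            break
        except scipy.linalg.LinAlgError:
            jitter = 1e-10 * max(1.0, np.trace(H) / H.shape[0]) * 10.0**attempt
            if attempt:
                warnings.warn(f"posterior precision factorisation: jitter {jitter:g}")
    else:
        raise np.linalg.LinAlgError(
            "posterior precision matrix could not be factorised; "
            "consider adding diagonal jitter or rescaling the targets"
        )
    Sigma = scipy.linalg.cho_solve(chol, np.eye(H.shape[0]))
    mu = beta * (Sigma @ PTy)
    logdet_H = 2.0 * np.sum(np.log(np.diag(chol[0])))
    return Sigma, mu, logdet_H


def _evidence(N, alpha, beta, rss, mu, logdet_H) -> float:
    """Log marginal likelihood log p(y | alpha, beta)."""
    return 0.5 * (
        np.sum(np.log(alpha))
        + N * np.log(beta)
        - beta * rss
        - float(mu @ (alpha * mu))
        - logdet_H
        - N * np.log(2.0 * np.pi)
    )


def rvm_fit(
    X,
    y,
    kernel: KernelSpec,
    max_iter: int = 1000,
    tol: float = 1e-6,
    prune_threshold: float = 1e12,
    beta_burn_in: int = 10,
) -> RVMModel:
    """Fit an RVM by evidence maximisation.

    Design matrix: a constant bias column plus one Laplacian-kernel column
    per training point (N + 1 bases for N points). Each iteration computes
    the weight posterior (Sigma, mu), then re-estimates

        gamma_i = 1 - alpha_i Sigma_ii,
        alpha_i = gamma_i / mu_i^2,
        beta    = (N - sum_i gamma_i) / ||y - Phi mu||^2,

    pruning bases whose alpha exceeds ``prune_threshold``. Iteration stops
    when max |delta log alpha| < tol or after ``max_iter`` sweeps.

    The noise precision is held at its initial value for the first
    ``beta_burn_in`` iterations: with all N + 1 bases still active the
    residual can be driven to zero, and re-estimating beta immediately
    collapses the fit onto that interpolating fixed point instead of a
    sparse one. Letting the weight precisions adapt first avoids this.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("RVM needs at least two training points")
    N = X.shape[0]
    Phi_full = np.hstack([np.ones((N, 1)), laplacian_gram(X, X, kernel.sigma)])
    PTP_full = Phi_full.T @ Phi_full
    PTy_full = Phi_full.T @ y
    active = np.arange(N + 1)
    alpha = np.full(N + 1, 1e-4)
    beta = 100.0 / max(float(np.var(y)), 1e-12)
    beta = min(beta, 1e10)
    evidence: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        Sigma, mu, logdet_H = _posterior(
            PTP_full[np.ix_(active, active)], PTy_full[active], alpha, beta
        )
        resid = y - Phi_full[:, active] @ mu
        rss = float(resid @ resid)
        gamma = 1.0 - alpha * np.diag(Sigma)
        evidence.append(_evidence(N, alpha, beta, rss, mu, logdet_H))
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_new = np.where(mu**2 > 0, gamma / mu**2, np.inf)
        alpha_new = np.where(alpha_new > 0, alpha_new, np.inf)
        if n_iter > beta_burn_in:
            beta_new = max(N - float(gamma.sum()), 1e-12) / max(rss, 1e-300)
            beta_new = min(beta_new, 1e12)
        else:
            beta_new = beta
        keep = np.isfinite(alpha_new) & (alpha_new <= prune_threshold)
        if not keep.any():
            raise RuntimeError("all basis functions were pruned; nothing to retain")
        converged = bool(
            np.max(np.abs(np.log(alpha_new[keep]) - np.log(alpha[keep]))) < tol
        ) and keep.all()
        active = active[keep]
        alpha = alpha_new[keep]
        beta = beta_new
        if converged:
            break
    # final posterior under the converged hyperparameters
    Sigma, mu, logdet_H = _posterior(
        PTP_full[np.ix_(active, active)], PTy_full[active], alpha, beta
    )
    bias_included = bool(active[0] == 0)
    rv_idx = active[1:] - 1 if bias_included else active - 1
    return RVMModel(
        relevance_vectors=X[rv_idx],
        weights=mu,
        alpha=alpha,
        beta=float(beta),
        bias_included=bias_included,
        kernel=kernel,
        evidence_history=evidence,
        n_iter=n_iter,
    )


def predict(model, X_new, clip: bool = False) -> np.ndarray:
    """Evaluate a fitted SVR or RVM model on new feature vectors.

    Predictions are raw regression outputs; pass ``clip=True`` to clamp them
    to [0, 1].
    """
    return model.predict(X_new, clip=clip)
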