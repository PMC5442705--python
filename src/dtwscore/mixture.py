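"""Gaussian finite mixture model fitted by EM, for cell-type clustering.

Cells are clustered on the expression values of the top-scoring gene(s)
(1 to 3 dimensions).  The mixture

    p(x) = sum_k w_k N(x; mu_k, Sigma_k)

is fitted by expectation-maximization under a declared covariance
structure:

* ``equal_variance``  — 1-D, one shared variance across components
* ``free_variance``   — 1-D, per-component variance
* ``diagonal``        — d in {2, 3}, per-component diagonal covariance
* ``full``            — d in {2, 3}, per-component full covariance

Model selection minimizes BIC = -2*loglik + p*log(n) (smaller is
better), ties broken toward smaller K and then fewer free parameters.

The implementation is deliberately self-contained: it exposes the
per-iteration log-likelihood trace (EM's monotonicity is a tested
contract), a deterministic quantile-split initialization, and a variance
floor of 1e-10 times the total data variance that prevents likelihood
blow-up when a component collapses onto coincident points.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .exceptions import DegenerateFitError, ValidationError

__all__ = ["MixtureFit", "em_fit", "select_model", "classify", "STRUCTURES"]

STRUCTURES = ("equal_variance", "free_variance", "diagonal", "full")

_VAR_FLOOR_REL = 1e-10


@dataclass
class MixtureFit:
    """Fitted Gaussian mixture: parameters, responsibilities, diagnostics."""

    K: int
    structure: str
    weights: np.ndarray          # (K,), simplex
    means: np.ndarray            # (K, d)
    covariances: np.ndarray      # (K, d, d)
    responsibilities: np.ndarray  # (n, K), rows sum to 1
    loglik_trace: np.ndarray     # per-iteration observed-data log-likelihood
    loglik: float
    bic: float
    n_params: int
    converged: bool
    n_iter: int
    assignments: np.ndarray = field(init=False)  # hard labels, argmax posterior

    def __post_init__(self) -> None:
        self.assignments = _argmax_lowest_tie(self.responsibilities)

    def summary(self) -> dict:
        return {
            "K": self.K,
            "structure": self.structure,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
            "loglik": self.loglik,
            "bic": self.bic,
            "n_params": self.n_params,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def _argmax_lowest_tie(post: np.ndarray) -> np.ndarray:
    # np.argmax already returns the first (lowest) index on exact ties
    return np.argmax(post, axis=1)


def _n_params(K: int, d: int, structure: str) -> int:
    mean_p = K * d
    weight_p = K - 1
    if structure == "equal_variance":
        cov_p = 1
    elif structure == "free_variance":
        cov_p = K
    elif structure == "diagonal":
        cov_p = K * d
    elif structure == "full":
        cov_p = K * d * (d + 1) // 2
    else:
        raise ValidationError(
            f"unknown covariance structure {structure!r}; expected one of {STRUCTURES}"
        )
    return mean_p + weight_p + cov_p


def _check_structure(structure: str, d: int) -> None:
    if structure not in STRUCTURES:
        raise ValidationError(
            f"unknown covariance structure {structure!r}; expected one of {STRUCTURES}"
        )
    if structure in ("equal_variance", "free_variance") and d != 1:
        raise ValidationError(f"structure {structure!r} is defined for d=1 only")
    if structure in ("diagonal", "full") and d == 1:
        raise ValidationError(
            f"structure {structure!r} needs d >= 2; use equal_variance or "
            "free_variance for univariate data"
        )


def _log_gauss(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    chol = linalg.cholesky(cov, lower=True)
    sol = linalg.solve_triangular(chol, (X - mean).T, lower=True)
    maha = np.sum(sol**2, axis=0)
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def _apply_structure(
    covs: np.ndarray, weights: np.ndarray, structure: str, floor: float
) -> np.ndarray:
    """Project covariances onto the declared structure (weighted average
    for the shared-variance case, zeroed off-diagonals for diagonal)."""
    K, d, _ = covs.shape
    if structure == "equal_variance":
        covs[:] = max(float(np.sum(weights * covs[:, 0, 0])), floor)
    elif structure == "free_variance":
        covs[:, 0, 0] = np.maximum(covs[:, 0, 0], floor)
    elif structure == "diagonal":
        for k in range(K):
            covs[k] = np.diag(np.maximum(np.diag(covs[k]), floor))
    else:  # full
        for k in range(K):
            covs[k] = covs[k] + floor * np.eye(d)
    return covs


def _init_params(
    X: np.ndarray, K: int, init: str, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, d = X.shape
    if init == "quantile_split":
        order = np.argsort(X[:, 0], kind="stable")
        blocks = np.array_split(order, K)
        means = np.array([X[b].mean(axis=0) for b in blocks])
        covs = np.array([np.atleast_2d(np.cov(X[b].T, bias=True)) for b in blocks])
        weights = np.array([len(b) / n for b in blocks])
    elif init == "random":
        idx = rng.choice(n, size=K, replace=False)
        means = X[idx]
        covs = np.array([np.atleast_2d(np.cov(X.T, bias=True))] * K)
        weights = np.full(K, 1.0 / K)
    else:
        raise ValidationError(
            f"unknown init {init!r}; expected 'quantile_split' or 'random'"
        )
    floor = _VAR_FLOOR_REL * max(float(np.var(X)), np.finfo(float).tiny)
    covs = covs.reshape(K, d, d) + floor * np.eye(d)
    return weights, means.reshape(K, d), covs


def _m_step(
    X: np.ndarray, post: np.ndarray, structure: str, floor: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, d = X.shape
    K = post.shape[1]
    nk = post.sum(axis=0) + 10 * np.finfo(float).tiny
    weights = nk / n
    means = (post.T @ X) / nk[:, None]
    covs = np.empty((K, d, d))
    for k in range(K):
        diff = X - means[k]
        covs[k] = (post[:, k][:, None] * diff).T @ diff / nk[k]
    covs = _apply_structure(covs, weights, structure, floor)
    return weights, means, covs


def em_fit(
    data,
    K: int,
    structure: str = "free_variance",
    init: str = "quantile_split",
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
) -> MixtureFit:
    """Fit a K-component Gaussian mixture by EM.

    ``data`` is an (n,) or (n, d) array with d in {1, 2, 3}.  Iteration
    stops when the log-likelihood improves by less than ``tol`` or after
    ``max_iter`` iterations.  ``quantile_split`` initialization (sort
    along the first dimension, cut into K equal-count blocks) is
    deterministic; ``random`` draws K points as initial means using
    ``seed``.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    if d not in (1, 2, 3):
        raise ValidationError(f"data dimension must be 1, 2 or 3, got {d}")
    if K < 1:
        raise ValidationError(f"K must be >= 1, got {K}")
    if n <= K:
        raise ValidationError(f"need more observations ({n}) than components ({K})")
    if tol <= 0:
        raise ValidationError(f"tol must be positive, got {tol}")
    _check_structure(structure, d)
    if K > 1 and np.allclose(X, X[0]):
        raise DegenerateFitError(
            "all observations identical: a multi-component mixture is degenerate"
        )

    rng = np.random.default_rng(seed)
    floor = _VAR_FLOOR_REL * max(float(np.var(X)), np.finfo(float).tiny)
    weights, means, covs = _init_params(X, K, init, rng)
    covs = _apply_structure(covs, weights, structure, floor)

    trace: list[float] = []
    converged = False
    post = np.full((n, K), 1.0 / K)
    for it in range(max_iter):
        # E-step
        log_prob = np.column_stack(
            [np.log(weights[k]) + _log_gauss(X, means[k], covs[k]) for k in range(K)]
        )
        log_norm = np.logaddexp.reduce(log_prob, axis=1)
        post = np.exp(log_prob - log_norm[:, None])
        loglik = float(np.sum(log_norm))
        trace.append(loglik)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        # M-step
        weights, means, covs = _m_step(X, post, structure, floor)

    p = _n_params(K, d, structure)
    loglik = trace[-1]
    return MixtureFit(
        K=K,
        structure=structure,
        weights=weights,
        means=means,
        covariances=covs,
        responsibilities=post,
        loglik_trace=np.array(trace),
        loglik=loglik,
        bic=-2.0 * loglik + p * np.log(n),
        n_params=p,
        converged=converged,
        n_iter=len(trace),
    )


def select_model(
    data,
    K_range=(1, 2, 3, 4),
    structures=None,
    init: str = "quantile_split",
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | None = None,
) -> MixtureFit:
    """Fit every (K, structure) combination and return the best by BIC.

    Default structures are the two univariate ones (equal_variance,
    free_variance) for 1-D data and diagonal/full otherwise.  Ties are
    broken toward smaller K, then fewer free parameters.  Combinations
    whose fit is degenerate are skipped; if every combination fails a
    :class:`DegenerateFitError` is raised.
    """
    X = np.asarray(data, dtype=float)
    d = 1 if X.ndim == 1 else X.shape[1]
    if structures is None:
        structures = (
            ("equal_variance", "free_variance") if d == 1 else ("diagonal", "full")
        )
    K_range = sorted(set(int(k) for k in K_range))
    if not K_range:
        raise ValidationError("K_range must be non-empty")

    candidates: list[MixtureFit] = []
    for K, structure in itertools.product(K_range, structures):
        try:
            candidates.append(
                em_fit(
                    X, K, structure=structure, init=init, tol=tol,
                    max_iter=max_iter, seed=seed,
                )
            )
        except (DegenerateFitError, ValidationError, linalg.LinAlgError):
            continue
    if not candidates:
        raise DegenerateFitError("every (K, structure) combination failed to fit")
    return min(candidates, key=lambda f: (f.bic, f.K, f.n_params))


def classify(fit: MixtureFit) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels (argmax posterior, ties to the lowest component index)
    and the posterior matrix itself."""
    return fit.assignments, fit.responsibilities
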