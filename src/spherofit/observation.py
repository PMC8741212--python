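"""Multivariate-normal observation model over spheroid measurements.

One measured spheroid contributes a 3-vector x = (R, phi, eta).  Observations
are modelled as x ~ N(mu, Sigma); the mechanistic connection substitutes
mu = m(theta), the steady-state map.  Sigma is a plug-in estimate (the sample
covariance of the relevant group, or the pooled covariance across seeding
densities for steady-state analysis) and is never co-estimated with theta.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import multivariate_normal

from .greenspan import (
    GreenspanParams,
    NoSteadyStateError,
    jacobian_steady_state,
    steady_state,
)

__all__ = [
    "SpheroidObservation",
    "SampleMoments",
    "observations_to_matrix",
    "sample_moments",
    "pooled_covariance",
    "log_likelihood",
    "log_likelihood_mechanistic",
    "grad_log_likelihood",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpheroidObservation:
    """One spheroid's measured size and structure with its metadata."""

    spheroid_id: str
    cell_line: str
    seeding_density: int
    day: float
    R: float
    phi: float
    eta: float
    flagged: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        if not self.R > 0:
            raise ValueError(f"R must be positive; got {self.R} ({self.spheroid_id})")
        if not (0.0 <= self.eta <= self.phi <= 1.0):
            raise ValueError(
                f"structure must satisfy 0 <= eta <= phi <= 1; got "
                f"phi={self.phi}, eta={self.eta} ({self.spheroid_id})"
            )
        if self.phi == 1.0 and not self.flagged:
            # phi = 1 means no visible cycling rim: tolerated but marked
            object.__setattr__(self, "flagged", True)

    def as_array(self) -> np.ndarray:
        return np.array([self.R, self.phi, self.eta])


@dataclass(frozen=True)
class SampleMoments:
    """Mean vector and covariance of (R, phi, eta) for one observation group."""

    mu: np.ndarray
    Sigma: np.ndarray
    n: int
    group_key: tuple | str = "pooled"


def observations_to_matrix(obs: list[SpheroidObservation]) -> np.ndarray:
    """Stack observations into an (n, 3) array of (R, phi, eta)."""
    return np.array([o.as_array() for o in obs])


def sample_moments(
    obs: list[SpheroidObservation], group_key: tuple | str = "pooled"
) -> SampleMoments:
    """Componentwise mean and unbiased (n-1) sample covariance of a group."""
    if len(obs) < 2:
        raise ValueError(f"need at least 2 observations for a covariance; got {len(obs)}")
    X = observations_to_matrix(obs)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in observations")
    mu = X.mean(axis=0)
    Sigma = np.cov(X, rowvar=False, ddof=1)
    return SampleMoments(mu=mu, Sigma=Sigma, n=len(obs), group_key=group_key)


def pooled_covariance(groups: list[SampleMoments]) -> np.ndarray:
    """Pooled covariance: (n_g - 1)-weighted average of group covariances."""
    if not groups:
        raise ValueError("no groups to pool")
    weights = np.array([g.n - 1 for g in groups], dtype=float)
    if np.any(weights < 1):
        raise ValueError("every group needs n >= 2")
    stacked = np.stack([g.Sigma for g in groups])
    return np.einsum("g,gij->ij", weights, stacked) / weights.sum()


def _check_sigma(Sigma: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Return (kept coordinate indices, dropped indices) for a possibly degenerate Sigma.

    Coordinates whose variance is (numerically) zero are dropped with a
    warning so that early-day groups where phi or eta is identically zero
    remain usable.
    """
    var = np.diag(Sigma)
    keep = [i for i in range(len(var)) if var[i] > 1e-14]
    dropped = [i for i in range(len(var)) if i not in keep]
    if dropped:
        logger.warning("dropping zero-variance coordinates %s from likelihood", dropped)
    return np.asarray(keep, dtype=int), dropped


def log_likelihood(mu: np.ndarray, Sigma: np.ndarray, X: np.ndarray) -> float:
    """Sum of trivariate-normal log-densities of the rows of X.

    X may be an (n, 3) array or a list of SpheroidObservation.
    """
    if isinstance(X, list):
        X = observations_to_matrix(X)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    mu = np.asarray(mu, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    keep, dropped = _check_sigma(Sigma)
    if dropped:
        mu = mu[keep]
        Sigma = Sigma[np.ix_(keep, keep)]
        X = X[:, keep]
    try:
        L = np.linalg.cholesky(Sigma)
    except np.linalg.LinAlgError:
        eigmin = float(np.linalg.eigvalsh(Sigma)[0])
        raise np.linalg.LinAlgError(
            f"covariance not positive definite (smallest eigenvalue {eigmin:.3g})"
        ) from None
    z = np.linalg.solve(L, (X - mu).T)
    n, k = X.shape
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return float(-0.5 * np.sum(z * z) - 0.5 * n * (k * np.log(2 * np.pi) + logdet))


def log_likelihood_mechanistic(
    gp: GreenspanParams, Sigma: np.ndarray, X: np.ndarray
) -> float:
    """Log-likelihood with the mean tied to the steady-state map, mu = m(theta).

    Returns -inf when no steady state exists, so optimizers can back away.
    """
    try:
        ss = steady_state(gp)
    except NoSteadyStateError:
        return -np.inf
    return log_likelihood(ss.as_array(), Sigma, X)


def grad_log_likelihood(gp: GreenspanParams, Sigma: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Gradient of the mechanistic log-likelihood via the chain rule.

    grad_theta l = J_m(theta)^T grad_mu l, with the mean-gradient in closed
    form, grad_mu l = n Sigma^{-1} (xbar - mu), and J_m from implicit
    differentiation of the steady-state system.
    """
    if isinstance(X, list):
        X = observations_to_matrix(X)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ss = steady_state(gp)
    mu = ss.as_array()
    n = X.shape[0]
    grad_mu = n * np.linalg.solve(Sigma, X.mean(axis=0) - mu)
    J = jacobian_steady_state(gp)  # d m / d theta, 3x3
    return J.T @ grad_mu
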