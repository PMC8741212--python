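"""Empirical linear model of phase-3 structure, fitted by total least squares.

During phase 3 the measured relationship between (R, phi, eta) is close to
linear.  The model is a line with a latent progression variable tau,

    (R(tau), phi(tau), eta(tau)) = (Rc_emp, phi_c, 0) + tau * q_hat,

anchored at the structure where necrosis first appears (eta = 0, tau = 0).
Each observation is the line point at its own latent tau_i plus multivariate
normal noise, so all three coordinates — including the progression variable —
are treated as noisy.  The exact maximum-likelihood fit is the principal axis
of the Sigma-whitened centred data, de-whitened back to measurement space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .observation import SpheroidObservation, observations_to_matrix
from .inference import LRTResult, _finalize_lrt

__all__ = [
    "LinearPhase3Params",
    "select_phase3",
    "fit_linear_tls",
    "lrt_shared_trajectory",
    "estimate_sigma_about_line",
]

logger = logging.getLogger(__name__)


@dataclass
class LinearPhase3Params:
    """Fitted phase-3 line: anchor at necrosis onset, unit direction, latent taus."""

    anchor: np.ndarray  # (Rc_emp, phi_c, 0)
    direction: np.ndarray  # unit 3-vector, eta component > 0
    tau: np.ndarray  # latent progression per observation (signed, 0 at onset)
    loglik: float
    Sigma: np.ndarray

    def __post_init__(self) -> None:
        assert abs(np.linalg.norm(self.direction) - 1.0) < 1e-9
        assert abs(self.anchor[2]) < 1e-9


def select_phase3(
    obs: list[SpheroidObservation], eta_min: float = 0.01
) -> list[SpheroidObservation]:
    """Observations with a measurable necrotic core (eta > eta_min)."""
    subset = [o for o in obs if o.eta > eta_min]
    logger.info("phase-3 selection: %d of %d observations (eta > %g)",
                len(subset), len(obs), eta_min)
    if not subset:
        raise ValueError(f"no observations with eta > {eta_min}: no phase-3 data")
    return subset


def _as_matrix(obs) -> np.ndarray:
    if isinstance(obs, list) and obs and isinstance(obs[0], SpheroidObservation):
        return observations_to_matrix(obs)
    return np.atleast_2d(np.asarray(obs, dtype=float))


def fit_linear_tls(obs, Sigma: np.ndarray) -> LinearPhase3Params:
    """Maximum-likelihood line through noisy phase-3 observations.

    Maximizes the N(a + tau_i q, Sigma) likelihood jointly over the line and
    the latent tau_i: whiten by the Cholesky factor of Sigma, take the leading
    principal axis of the centred cloud, and map back.  The anchor is the
    point on the line where eta = 0; the direction is canonically signed so
    tau increases with eta.  Negative fitted taus (observations "before"
    onset) are reported, not clipped.
    """
    X = _as_matrix(obs)
    n = X.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 phase-3 observations; got {n}")
    Sigma = np.asarray(Sigma, dtype=float)
    L = np.linalg.cholesky(Sigma)
    Z = np.linalg.solve(L, (X - X.mean(axis=0)).T).T  # whitened, centred

    cov = Z.T @ Z / n
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or (evals[-1] - evals[-2]) / max(evals[-1], 1e-300) < 1e-12:
        raise RuntimeError(
            "degenerate direction: data are isotropic after whitening "
            f"(leading eigenvalues {evals[-1]:.6g}, {evals[-2]:.6g})"
        )
    u = evecs[:, -1]  # whitened principal axis (unit)

    # maximized log-likelihood: orthogonal whitened residuals only remain
    resid2 = float(np.sum(Z**2) - np.sum((Z @ u) ** 2))
    _, logdet = np.linalg.slogdet(Sigma)
    loglik = -0.5 * resid2 - 0.5 * n * (3 * np.log(2 * np.pi) + logdet)

    q = L @ u
    q = q / np.linalg.norm(q)
    if q[2] < 0:  # canonical sign: tau increases with eta
        q = -q
        u = -u
    if abs(q[2]) < 1e-12:
        raise RuntimeError("fitted line is parallel to the eta = 0 plane: no anchor")

    center = X.mean(axis=0)
    t_anchor = -center[2] / q[2]
    anchor = center + t_anchor * q
    anchor[2] = 0.0  # exact by construction, kill rounding

    # fitted latent points: whitened projection, mapped back, measured from anchor
    t_white = Z @ u
    fitted = center + np.outer(t_white, (L @ u))
    tau = (fitted - anchor) @ q
    return LinearPhase3Params(anchor=anchor, direction=q, tau=tau, loglik=loglik, Sigma=Sigma)


def estimate_sigma_about_line(obs, n_iter: int = 2, floor_frac: float = 1.0) -> np.ndarray:
    """Plug-in covariance for the TLS fit: residual covariance, iterated.

    Starts from the raw sample covariance, then alternates fit -> covariance
    of residuals about the line -> refit, n_iter times.  TLS residuals are
    Sigma-orthogonal to the line, so their covariance is rank deficient along
    it; the missing along-line eigenvalue is floored at the smallest
    substantial residual eigenvalue to keep the metric positive definite.
    """
    X = _as_matrix(obs)
    # start from per-coordinate scales only: whitening with the full raw
    # covariance would erase the line direction itself
    Sigma = np.diag(np.var(X, axis=0, ddof=1))
    for it in range(n_iter):
        fit = fit_linear_tls(X, Sigma)
        fitted = fit.anchor + np.outer(fit.tau, fit.direction)
        resid = X - fitted
        S = resid.T @ resid / max(len(X) - 1, 1)
        evals, evecs = np.linalg.eigh(S)
        floor = floor_frac * max(evals[1], 1e-12)  # second-smallest: the rank-2 part
        evals = np.maximum(evals, floor)
        Sigma = (evecs * evals) @ evecs.T
        logger.info("TLS Sigma iteration %d: eigenvalues %s", it + 1, evals)
    return Sigma


def lrt_shared_trajectory(
    groups_by_density: dict, Sigma: np.ndarray | None = None
) -> LRTResult:
    """Test that one phase-3 line describes every seeding density.

    Null: shared (anchor, direction) across groups; alternative: one line per
    group.  Latent taus are free per observation under both hypotheses.  The
    line has 4 free parameters (2 anchor components on the eta = 0 plane plus
    a direction on the unit sphere), so nu = 4 (G - 1).  Sigma is plug-in and
    shared by both fits; when not supplied it is estimated from the pooled
    data about a preliminary joint fit.
    """
    groups = {k: _as_matrix(v) for k, v in groups_by_density.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    X_all = np.vstack(list(groups.values()))
    if Sigma is None:
        Sigma = estimate_sigma_about_line(X_all)
    joint = fit_linear_tls(X_all, Sigma)
    l_alt = sum(fit_linear_tls(X, Sigma).loglik for X in groups.values())
    T = 2.0 * (l_alt - joint.loglik)
    nu = 4 * (len(groups) - 1)
    return _finalize_lrt(T, nu)
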