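"""Likelihood-based inference: MLE, profiles, likelihood-ratio tests, regions.

All routines work on a log-likelihood objective ``l(theta)`` to be maximized.
Approximate confidence sets come from Wilks' theorem: an alpha-level region is
``{theta : l(theta) >= l(theta_hat) - Delta_{nu,alpha}/2}`` with Delta the
chi-squared quantile.  Group comparisons use the likelihood-ratio statistic
``T = 2(-l(theta*_joint) + sum_g l(theta_g))`` with degrees of freedom equal
to the number of additional free parameters under the alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
from scipy.optimize import brentq, minimize, minimize_scalar
from scipy.stats import chi2, qmc

from .greenspan import GreenspanParams, invert_steady_state
from .observation import log_likelihood, log_likelihood_mechanistic

__all__ = [
    "MLEResult",
    "ProfileResult",
    "ConfidenceRegion",
    "LRTResult",
    "MeanModel",
    "SteadyStateModel",
    "maximize_likelihood",
    "wilks_threshold",
    "profile_parameter",
    "lrt_group_equivalence",
    "lrt_single_parameter",
    "trace_confidence_region",
    "slice_region_3d",
]


# --------------------------------------------------------------------------
# results


@dataclass
class MLEResult:
    theta_hat: np.ndarray
    loglik_hat: float
    converged: bool
    n_restarts_used: int


@dataclass
class ProfileResult:
    psi_grid: np.ndarray
    profile_values: np.ndarray  # normalised, <= 0, max 0 at the MLE's psi
    ci: tuple[float, float]
    nuisance_paths: np.ndarray
    level: float
    lower_unbounded: bool = False
    upper_unbounded: bool = False


@dataclass
class ConfidenceRegion:
    level: float
    boundary_points: np.ndarray  # (n, 2) ordered polyline
    loglik_level: float
    closed: bool
    fixed_value: float | None = None  # for 3-D slices: the fixed coordinate
    fixed_index: int | None = None


@dataclass
class LRTResult:
    T: float
    nu: int
    p: float


# --------------------------------------------------------------------------
# model specifications: a log-likelihood over theta plus fitting conveniences
#
# "data" is always a pair (X, Sigma): an (n, 3) array of observations and the
# plug-in covariance used for that group.


@dataclass
class MeanModel:
    """Statistical model: theta is the free 3-vector mean mu."""

    bounds: Sequence[tuple[float, float]] = (
        (1.0, 2000.0),
        (1e-6, 1.0 - 1e-6),
        (1e-6, 1.0 - 1e-6),
    )

    @property
    def dim(self) -> int:
        return 3

    def loglik(self, theta: np.ndarray, data: tuple) -> float:
        X, Sigma = data
        try:
            return log_likelihood(np.asarray(theta), Sigma, X)
        except np.linalg.LinAlgError:
            return -np.inf

    def initial(self, data: tuple) -> np.ndarray:
        X, _ = data
        return np.atleast_2d(X).mean(axis=0)

    def fit(self, datasets: list[tuple]) -> MLEResult:
        # shared Sigma across datasets -> MLE is the precision-weighted mean;
        # with group-specific Sigma the weighted combination below is exact too
        Ws, bs, ll = [], [], 0.0
        for X, Sigma in datasets:
            X = np.atleast_2d(X)
            W = np.linalg.inv(Sigma) * X.shape[0]
            Ws.append(W)
            bs.append(W @ X.mean(axis=0))
        mu = np.linalg.solve(np.sum(Ws, axis=0), np.sum(bs, axis=0))
        ll = sum(self.loglik(mu, d) for d in datasets)
        return MLEResult(theta_hat=mu, loglik_hat=ll, converged=True, n_restarts_used=0)


@dataclass
class SteadyStateModel:
    """Mechanistic model: theta = (Q, Rc, gamma), mean tied to the limiting structure."""

    bounds: Sequence[tuple[float, float]] = (
        (1e-3, 1.0 - 1e-3),
        (1.0, 1500.0),
        (1e-3, 50.0),
    )

    @property
    def dim(self) -> int:
        return 3

    def loglik(self, theta: np.ndarray, data: tuple) -> float:
        X, Sigma = data
        Q, Rc, gamma = theta
        lo = [b[0] for b in self.bounds]
        hi = [b[1] for b in self.bounds]
        if not all(l <= t <= h for t, l, h in zip(theta, lo, hi)):
            return -np.inf
        try:
            gp = GreenspanParams(float(Q), float(Rc), float(gamma))
        except ValueError:
            return -np.inf
        return log_likelihood_mechanistic(gp, Sigma, X)

    def initial(self, data: tuple) -> np.ndarray:
        X, _ = data
        mu = np.atleast_2d(X).mean(axis=0)
        try:
            gp = invert_steady_state(*mu)
            return gp.as_array()
        except ValueError:
            return np.array([0.7, max(mu[0], 2.0) / 2.0, 0.8])

    def fit(self, datasets: list[tuple], n_starts: int = 1, seed: int | None = None) -> MLEResult:
        def obj(theta: np.ndarray) -> float:
            return sum(self.loglik(theta, d) for d in datasets)

        Xall = np.vstack([np.atleast_2d(X) for X, _ in datasets])
        theta0 = self.initial((Xall, None))
        return maximize_likelihood(obj, theta0, self.bounds, n_starts=n_starts, seed=seed)


# --------------------------------------------------------------------------
# core routines


def maximize_likelihood(
    objective: Callable[[np.ndarray], float],
    theta0: np.ndarray,
    bounds: Sequence[tuple[float, float]],
    n_starts: int = 10,
    seed: int | None = None,
    xatol: float = 1e-10,
    fatol: float = 1e-12,
) -> MLEResult:
    """Maximize a log-likelihood with a multi-start simplex search.

    The first start is theta0; the remaining n_starts - 1 are a Latin
    hypercube over the bounds.  The best local maximizer is returned.
    """
    theta0 = np.asarray(theta0, dtype=float)
    if not np.isfinite(objective(theta0)):
        raise ValueError(f"objective not finite at the initial point {theta0}")
    bounds = list(bounds)
    starts = [theta0]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
        lo = np.array([b[0] for b in bounds])
        hi = np.array([b[1] for b in bounds])
        extra = qmc.scale(sampler.random(n_starts - 1), lo, hi)
        starts.extend(list(extra))

    best: MLEResult | None = None
    failures: list[str] = []
    for x0 in starts:
        if not np.isfinite(objective(np.asarray(x0))):
            failures.append(f"start {x0}: objective not finite")
            continue
        res = minimize(
            lambda th: -objective(th),
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": xatol, "fatol": fatol, "maxiter": 5000},
        )
        if not np.isfinite(res.fun):
            failures.append(f"start {x0}: {res.message}")
            continue
        cand = MLEResult(
            theta_hat=res.x, loglik_hat=-res.fun, converged=bool(res.success),
            n_restarts_used=len(starts),
        )
        if best is None or cand.loglik_hat > best.loglik_hat:
            best = cand
    if best is None:
        raise RuntimeError("all optimizer starts failed: " + "; ".join(failures))
    return best


def wilks_threshold(alpha: float, nu: int) -> float:
    """Log-likelihood drop Delta_{nu,alpha}/2 defining an alpha-level region."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1); got {alpha}")
    if nu < 1:
        raise ValueError(f"nu must be >= 1; got {nu}")
    return float(chi2.ppf(alpha, df=nu) / 2.0)


def observed_information(
    objective: Callable[[np.ndarray], float],
    theta: np.ndarray,
    rel_step: float = 1e-4,
) -> np.ndarray:
    """Negative Hessian of the log-likelihood by central finite differences."""
    theta = np.asarray(theta, dtype=float)
    d = len(theta)
    h = rel_step * np.maximum(np.abs(theta), 1e-3)
    H = np.empty((d, d))
    f0 = objective(theta)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        H[i, i] = (objective(theta + ei) - 2 * f0 + objective(theta - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                objective(theta + ei + ej) - objective(theta + ei - ej)
                - objective(theta - ei + ej) + objective(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    return -H


def _profile_value(
    objective: Callable[[np.ndarray], float],
    index: int,
    psi: float,
    lam0: np.ndarray,
    bounds: Sequence[tuple[float, float]],
) -> tuple[float, np.ndarray]:
    """sup over nuisance of the objective at fixed interest value psi."""
    free = [i for i in range(len(bounds)) if i != index]
    if not free:
        theta = np.array([psi])
        return objective(theta), np.empty(0)

    def embed(lam: np.ndarray) -> np.ndarray:
        theta = np.empty(len(bounds))
        theta[index] = psi
        theta[free] = lam
        return theta

    res = minimize(
        lambda lam: -objective(embed(lam)),
        lam0,
        method="Nelder-Mead",
        bounds=[bounds[i] for i in free],
        options={"xatol": 1e-7, "fatol": 1e-8, "maxiter": 2000},
    )
    return -res.fun, res.x


def profile_parameter(
    objective: Callable[[np.ndarray], float],
    mle: MLEResult,
    index: int,
    bounds: Sequence[tuple[float, float]],
    se: float | None = None,
    n_grid: int = 41,
    alpha: float = 0.95,
    span_se: float = 4.0,
) -> ProfileResult:
    """Normalised profile log-likelihood of one parameter with its Wilks CI.

    The grid spans the MLE +/- span_se standard errors (se estimated from a
    local quadratic fit when not supplied) and is extended outward until the
    profile drops below the chi-squared(1) threshold or hits the parameter
    bounds.  Nuisance optimizations are warm-started from the adjacent grid
    point, sweeping outward from the MLE in both directions; CI endpoints are
    refined by root bisection on the profile itself.
    """
    theta_hat = np.asarray(mle.theta_hat, dtype=float)
    d = len(theta_hat)
    free = [i for i in range(d) if i != index]
    psi_hat = theta_hat[index]
    lo, hi = bounds[index]
    thr = wilks_threshold(alpha, 1)

    if se is None:
        # plug-in profile se from the observed information (accounts for nuisance)
        H = observed_information(objective, theta_hat)
        try:
            cov = np.linalg.inv(H)
            se = float(np.sqrt(cov[index, index])) if cov[index, index] > 0 else None
        except np.linalg.LinAlgError:
            se = None
        if se is None:
            se = 0.25 * max(abs(psi_hat), 1.0)

    def sweep(direction: int) -> tuple[list[float], list[float], list[np.ndarray], bool]:
        """Walk outward from the MLE; return grid, values, nuisances, crossed-flag."""
        step = direction * span_se * se / ((n_grid - 1) / 2)
        psis: list[float] = []
        vals: list[float] = []
        lams: list[np.ndarray] = []
        lam = theta_hat[free].copy()
        psi = psi_hat
        crossed = False
        max_steps = 6 * n_grid
        for _ in range(max_steps):
            psi = psi + step
            if psi <= lo or psi >= hi:
                break
            val, lam = _profile_value(objective, index, psi, lam, bounds)
            psis.append(psi)
            vals.append(val - mle.loglik_hat)
            lams.append(lam.copy())
            if vals[-1] < -thr - 1.0:
                crossed = True
                break
        return psis, vals, lams, crossed

    up_psi, up_val, up_lam, up_crossed = sweep(+1)
    dn_psi, dn_val, dn_lam, dn_crossed = sweep(-1)

    psi_grid = np.array(dn_psi[::-1] + [psi_hat] + up_psi)
    profile = np.array(dn_val[::-1] + [0.0] + up_val)
    lam_pad = theta_hat[free]
    nuisance = np.array(dn_lam[::-1] + [lam_pad] + up_lam) if free else np.empty((len(psi_grid), 0))
    profile = np.minimum(profile, 0.0)  # optimizer jitter guard

    def endpoint(side: int) -> tuple[float, bool]:
        # side -1: lower, +1: upper
        if side < 0:
            g, v = psi_grid[psi_grid <= psi_hat], profile[psi_grid <= psi_hat]
            g, v = g[::-1], v[::-1]
            crossed = dn_crossed or (len(v) and v[-1] < -thr)
        else:
            g, v = psi_grid[psi_grid >= psi_hat], profile[psi_grid >= psi_hat]
            crossed = up_crossed or (len(v) and v[-1] < -thr)
        below = np.nonzero(v < -thr)[0]
        if len(below) == 0:
            return (lo if side < 0 else hi), not crossed
        j = below[0]
        a, b = g[j - 1], g[j]

        lam_start = theta_hat[free].copy()

        def f(psi: float) -> float:
            val, _ = _profile_value(objective, index, psi, lam_start, bounds)
            return val - mle.loglik_hat + thr

        try:
            root = brentq(f, a, b, xtol=1e-8 * max(abs(psi_hat), 1.0))
        except ValueError:
            root = 0.5 * (a + b)
        return float(root), False

    lo_ci, lo_unb = endpoint(-1)
    hi_ci, hi_unb = endpoint(+1)
    return ProfileResult(
        psi_grid=psi_grid,
        profile_values=profile,
        ci=(lo_ci, hi_ci),
        nuisance_paths=nuisance,
        level=alpha,
        lower_unbounded=bool(lo_unb),
        upper_unbounded=bool(hi_unb),
    )


# --------------------------------------------------------------------------
# likelihood-ratio tests


def _fit_model(model: Any, datasets: list[tuple], **kw: Any) -> MLEResult:
    return model.fit(datasets, **kw) if kw else model.fit(datasets)


def lrt_group_equivalence(datasets_by_group: dict[Any, list[tuple]], model: Any) -> LRTResult:
    """Test that one shared parameter vector describes every group.

    Null: a single theta fitted to all groups jointly (each group keeps its
    own Sigma).  Alternative: a free theta per group.
    T = 2(-l_joint + sum_g l_g) ~ chi2((G-1) dim(theta)).
    """
    groups = list(datasets_by_group.values())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    joint = _fit_model(model, [d for g in groups for d in g])
    per_group = [_fit_model(model, g) for g in groups]
    T = 2.0 * (-joint.loglik_hat + sum(r.loglik_hat for r in per_group))
    nu = (len(groups) - 1) * model.dim
    return _finalize_lrt(T, nu)


def lrt_single_parameter(
    datasets_by_group: dict[Any, list[tuple]], model: Any, index: int
) -> LRTResult:
    """Test equality of one parameter across groups, others free per group.

    Null: groups share only theta[index]; each group keeps its own remaining
    parameters.  The shared value is found by maximizing the sum of per-group
    profile log-likelihoods over the interest parameter (the nuisances
    separate across groups).  nu = G - 1.
    """
    groups = list(datasets_by_group.values())
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    fits = [_fit_model(model, g) for g in groups]
    l_alt = sum(r.loglik_hat for r in fits)

    bounds = list(model.bounds)

    def group_objective(g: list[tuple]) -> Callable[[np.ndarray], float]:
        return lambda th: sum(model.loglik(th, d) for d in g)

    objectives = [group_objective(g) for g in groups]
    lam_starts = [r.theta_hat[[i for i in range(model.dim) if i != index]] for r in fits]

    def null_at(psi: float) -> float:
        total = 0.0
        for obj, lam0 in zip(objectives, lam_starts):
            val, _ = _profile_value(obj, index, psi, lam0, bounds)
            total += val
        return total

    psi_vals = [r.theta_hat[index] for r in fits]
    lo = max(bounds[index][0], min(psi_vals) - abs(max(psi_vals) - min(psi_vals)))
    hi = min(bounds[index][1], max(psi_vals) + abs(max(psi_vals) - min(psi_vals)))
    if hi <= lo:
        lo, hi = bounds[index]
    res = minimize_scalar(lambda p: -null_at(p), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    l_null = -res.fun
    T = 2.0 * (l_alt - l_null)
    nu = len(groups) - 1
    return _finalize_lrt(T, nu)


def _finalize_lrt(T: float, nu: int) -> LRTResult:
    if T < 0:
        if T > -1e-6:
            warnings.warn(f"test statistic {T:.3g} clipped to 0 (optimizer noise)")
            T = 0.0
        else:
            raise RuntimeError(
                f"negative test statistic {T:.6g}: the joint fit beat the per-group "
                "fits, indicating an optimization failure"
            )
    p = float(chi2.sf(T, df=nu))
    return LRTResult(T=float(T), nu=nu, p=p)


# --------------------------------------------------------------------------
# confidence-region tracing


def _fd_gradient(f: Callable[[np.ndarray], float], x: np.ndarray, scale: np.ndarray) -> np.ndarray:
    g = np.empty(len(x))
    for i in range(len(x)):
        h = 1e-6 * scale[i]
        e = np.zeros(len(x))
        e[i] = h
        g[i] = (f(x + e) - f(x - e)) / (2 * h)
    return g


def trace_confidence_region(
    objective_2d: Callable[[np.ndarray], float],
    mle: np.ndarray,
    alpha: float = 0.95,
    threshold: float | None = None,
    grad: Callable[[np.ndarray], np.ndarray] | None = None,
    ray: np.ndarray | None = None,
    n_steps_max: int = 4000,
    step_frac: float = 0.02,
) -> ConfidenceRegion:
    """Trace the closed boundary of a 2-D likelihood confidence region.

    A boundary point theta0 is found by bisection along a ray from the MLE to
    the contour l = l_hat - threshold; the boundary is then followed by
    integrating the rotated-gradient (likelihood-annihilating) field with a
    Newton re-projection onto the contour after every step, and terminates
    when the path returns to within a step of theta0.
    """
    mle = np.asarray(mle, dtype=float)
    l_hat = objective_2d(mle)
    if threshold is None:
        threshold = wilks_threshold(alpha, 2)
    target = l_hat - threshold

    # trace in standardized coordinates u = (theta - mle)/scale so the contour
    # is near-circular; scale = plug-in standard errors where available
    H = observed_information(objective_2d, mle)
    try:
        cov = np.linalg.inv(H)
        diag = np.diag(cov)
        scale = np.sqrt(diag) if np.all(diag > 0) else np.maximum(np.abs(mle), 1e-3)
    except np.linalg.LinAlgError:
        scale = np.maximum(np.abs(mle), 1e-3)

    def f(u: np.ndarray) -> float:
        return objective_2d(mle + u * scale)

    if grad is not None:
        def g(u: np.ndarray) -> np.ndarray:
            return grad(mle + u * scale) * scale
    else:
        def g(u: np.ndarray) -> np.ndarray:
            gu = np.empty(2)
            for i in range(2):
                e = np.zeros(2)
                e[i] = 1e-6 * max(1.0, abs(u[i]))
                gu[i] = (f(u + e) - f(u - e)) / (2 * e[i])
            return gu

    direction = np.array([1.0, 0.0]) if ray is None else np.asarray(ray, float) / np.linalg.norm(ray)

    def along(t: float) -> float:
        return f(t * direction) - target

    t_hi = 1e-3
    while along(t_hi) > 0:
        t_hi *= 2.0
        if t_hi > 1e6:
            raise RuntimeError("could not bracket the region boundary along the ray")
    t0 = brentq(along, t_hi / 2.0 if along(t_hi / 2.0) > 0 else 0.0, t_hi, xtol=1e-13)
    u0 = t0 * direction

    def project(u: np.ndarray) -> np.ndarray:
        # Newton correction along the gradient back onto the contour
        for _ in range(50):
            r = f(u) - target
            if abs(r) < 1e-9:
                break
            gu = g(u)
            n2 = float(gu @ gu)
            if n2 == 0:
                break
            u = u - gu * (r / n2)
        return u

    rot = np.array([[0.0, -1.0], [1.0, 0.0]])
    h = step_frac * np.linalg.norm(u0)

    def vel(u: np.ndarray) -> np.ndarray:
        v = rot @ g(u)
        n = np.linalg.norm(v)
        if n == 0:
            raise RuntimeError("zero gradient on the contour: cannot trace")
        return v / n

    pts = [u0]
    u = u0.copy()
    closed = False
    swept = 0.0
    ang_prev = np.arctan2(u0[1], u0[0])
    for _ in range(n_steps_max):
        # RK4 along the unit-speed annihilating field, then re-project
        k1 = vel(u)
        k2 = vel(u + 0.5 * h * k1)
        k3 = vel(u + 0.5 * h * k2)
        k4 = vel(u + h * k3)
        u = project(u + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4))
        pts.append(u.copy())
        ang = np.arctan2(u[1], u[0])
        d_ang = (ang - ang_prev + np.pi) % (2 * np.pi) - np.pi
        swept += d_ang
        ang_prev = ang
        if abs(swept) > 1.75 * np.pi and np.linalg.norm(u - u0) < 1.5 * h:
            closed = True
            break
    boundary = np.array(pts) * scale + mle
    if closed:
        boundary = np.vstack([boundary, u0 * scale + mle])  # close the polyline
    return ConfidenceRegion(
        level=alpha, boundary_points=boundary, loglik_level=float(target), closed=closed
    )


def slice_region_3d(
    objective_3d: Callable[[np.ndarray], float],
    mle: np.ndarray,
    alpha: float,
    n_slices: int,
    bounds: Sequence[tuple[float, float]],
    slice_index: int = 2,
) -> list[ConfidenceRegion]:
    """3-D confidence region as a stack of 2-D slices.

    One coordinate is fixed on a grid through the MLE; each slice's contour is
    traced at the 3-degree-of-freedom threshold.  Slices whose conditional
    maximum falls below the threshold are returned empty.
    """
    mle = np.asarray(mle, dtype=float)
    l_hat = objective_3d(mle)
    thr = wilks_threshold(alpha, 3)
    target = l_hat - thr
    free = [i for i in range(3) if i != slice_index]
    lo, hi = bounds[slice_index]
    # grid through the MLE spanning the region: +/- 4 plug-in standard errors
    H = observed_information(objective_3d, mle)
    try:
        var = np.linalg.inv(H)[slice_index, slice_index]
        span = 4.0 * np.sqrt(var) if var > 0 else 0.25 * (hi - lo)
    except np.linalg.LinAlgError:
        span = 0.25 * (hi - lo)
    grid = np.linspace(
        max(lo, mle[slice_index] - span), min(hi, mle[slice_index] + span), n_slices
    )
    # ensure the MLE's own slice is present
    grid = np.unique(np.append(grid, mle[slice_index]))

    regions: list[ConfidenceRegion] = []
    for val in grid:
        def obj2(xy: np.ndarray, _val: float = val) -> float:
            theta = np.empty(3)
            theta[slice_index] = _val
            theta[free] = xy
            return objective_3d(theta)

        res = minimize(
            lambda xy: -obj2(xy), mle[free], method="Nelder-Mead",
            bounds=[bounds[i] for i in free],
            options={"xatol": 1e-9, "fatol": 1e-10},
        )
        l_cond = -res.fun
        if not np.isfinite(l_cond) or l_cond < target:
            regions.append(
                ConfidenceRegion(
                    level=alpha, boundary_points=np.empty((0, 2)),
                    loglik_level=float(target), closed=True,
                    fixed_value=float(val), fixed_index=slice_index,
                )
            )
            continue
        reg = trace_confidence_region(
            obj2, res.x, alpha=alpha, threshold=l_cond - target,
        )
        regions.append(
            ConfidenceRegion(
                level=alpha, boundary_points=reg.boundary_points,
                loglik_level=float(target), closed=reg.closed,
                fixed_value=float(val), fixed_index=slice_index,
            )
        )
    return regions
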