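"""Greenspan model of avascular spheroid structure and growth.

The model reduces a growing spheroid to its outer radius ``R`` (µm) and two
dimensionless internal interfaces: the relative radius of the cell-cycle
inhibited region ``phi = Ri/R`` and of the necrotic core ``eta = Rn/R``,
with ``0 <= eta <= phi < 1``.  Nutrient and waste species are assumed to be
at diffusive equilibrium, so the inner structure is an algebraic function of
the outer radius alone, controlled by two structural parameters:

* ``Q`` — dimensionless balance between nutrient supply/consumption and
  inhibitor production/clearance; the regime of interest requires ``Q < 1``
  (the inhibited region appears before the necrotic core);
* ``Rc`` — the critical radius (µm) at which necrosis first occurs.

Growth follows a mass balance between proliferation in the cycling rim and
mass loss from the necrotic core,

    dR/dt = (s/3) (1 - phi^3) R - (s/3) gamma eta^3 R,

with per-volume proliferation rate ``s`` (1/d) and loss/growth ratio
``gamma = lambda/s``.  Setting dR/dt = 0 together with the structural system
yields the steady (limiting) structure ``(Rbar, phibar, etabar)``, a map from
``theta = (Q, Rc, gamma)`` that is invertible in closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "DimensionalParams",
    "GrowthParams",
    "StructuralParams",
    "GreenspanParams",
    "Structure",
    "SteadyState",
    "Trajectory",
    "compose_Q",
    "compose_gamma",
    "structure_radius",
    "solve_eta_phase3",
    "solve_phi_phase3",
    "growth_rate",
    "simulate_growth",
    "steady_state",
    "invert_steady_state",
    "invert_structure",
    "jacobian_steady_state",
    "NoSteadyStateError",
]

_ROOT_XTOL = 1e-12


class NoSteadyStateError(RuntimeError):
    """Raised when no phase-3 steady state exists for the given parameters."""


@dataclass(frozen=True)
class DimensionalParams:
    """Dimensional rates underlying the composite parameter Q.

    beta_* describe the growth inhibitor (production rate mol/d, diffusivity
    µm²/d, critical concentration mol/µm³); omega_* describe the nutrient
    (consumption rate, diffusivity, far-field and critical concentrations).
    """

    beta_prod: float
    beta_diff: float
    beta_crit: float
    omega_cons: float
    omega_diff: float
    omega_inf: float
    omega_crit: float

    def __post_init__(self) -> None:
        vals = [
            self.beta_prod, self.beta_diff, self.beta_crit,
            self.omega_cons, self.omega_diff, self.omega_inf, self.omega_crit,
        ]
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise ValueError("all dimensional parameters must be finite and positive")
        if self.omega_inf <= self.omega_crit:
            raise ValueError("far-field nutrient concentration must exceed the critical one")


@dataclass(frozen=True)
class GrowthParams:
    """Per-volume proliferation rate s and necrotic loss rate lambda (1/d)."""

    s: float
    lambda_loss: float

    def __post_init__(self) -> None:
        if self.s <= 0 or self.lambda_loss <= 0:
            raise ValueError("rates s and lambda must be positive")


@dataclass(frozen=True)
class StructuralParams:
    """Structural pair (Q, Rc): dimensionless balance and necrosis-onset radius (µm)."""

    Q: float
    Rc: float

    def __post_init__(self) -> None:
        if not (0.0 < self.Q < 1.0):
            raise ValueError(f"Q must lie in (0, 1); got {self.Q}")
        if self.Rc <= 0:
            raise ValueError(f"Rc must be positive; got {self.Rc}")


@dataclass(frozen=True)
class GreenspanParams:
    """Full mechanistic triple theta = (Q, Rc, gamma)."""

    Q: float
    Rc: float
    gamma: float

    def __post_init__(self) -> None:
        if not (0.0 < self.Q < 1.0):
            raise ValueError(f"Q must lie in (0, 1); got {self.Q}")
        if self.Rc <= 0:
            raise ValueError(f"Rc must be positive; got {self.Rc}")
        if self.gamma <= 0:
            raise ValueError(f"gamma must be positive; got {self.gamma}")

    @property
    def structural(self) -> StructuralParams:
        return StructuralParams(self.Q, self.Rc)

    def as_array(self) -> np.ndarray:
        return np.array([self.Q, self.Rc, self.gamma])


@dataclass(frozen=True)
class Structure:
    """Inner structure at one instant: relative inhibited and necrotic radii."""

    phi: float
    eta: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.eta <= self.phi < 1.0):
            raise ValueError(f"structure must satisfy 0 <= eta <= phi < 1; got {self}")


@dataclass(frozen=True)
class SteadyState:
    """Limiting structure (Rbar, phibar, etabar) with auxiliary ratio rho = etabar/phibar."""

    R_bar: float
    phi_bar: float
    eta_bar: float
    rho: float

    def as_array(self) -> np.ndarray:
        return np.array([self.R_bar, self.phi_bar, self.eta_bar])


@dataclass(frozen=True)
class Trajectory:
    """Radius and structure sampled on a time grid (days, µm)."""

    times: np.ndarray
    radii: np.ndarray
    structures: list[Structure]


def compose_Q(p: DimensionalParams) -> float:
    """Compose the dimensionless balance Q from the dimensional rates.

    Q² = [ω_cons / (ω_diff (ω_inf − ω_crit))] · [β_crit β_diff / β_prod];
    the model regime requires Q < 1.
    """
    q2 = (p.omega_cons / (p.omega_diff * (p.omega_inf - p.omega_crit))) * (
        p.beta_crit * p.beta_diff / p.beta_prod
    )
    if q2 >= 1.0:
        raise ValueError(
            f"composed Q² = {q2:.6g} >= 1: the inhibited region must form before "
            "the necrotic region, so the model requires Q < 1"
        )
    return float(np.sqrt(q2))


def compose_gamma(g: GrowthParams) -> float:
    """Loss-to-growth ratio gamma = lambda / s."""
    return g.lambda_loss / g.s


def _fs_eta(eta: float, R: float, Rc: float) -> float:
    # first component of the phase-3 structural system
    return 2 * R * R * eta**3 - 3 * R * R * eta**2 + R * R - Rc * Rc


def _fs_phi(phi: float, eta: float, R: float, Q: float, Rc: float) -> float:
    # second component of the phase-3 structural system
    return R * R * phi**3 + (Q * Q * Rc * Rc - R * R * (1 + 2 * eta**3)) * phi + 2 * eta**3 * R * R


def solve_eta_phase3(R: float, Rc: float) -> float:
    """Relative necrotic radius in phase 3 (R > Rc).

    The cubic 2R²η³ − 3R²η² + R² − Rc² = 0 factorises as
    (1−η)²(1+2η) = Rc²/R², whose left side is strictly decreasing on (0, 1),
    so the root in (0, 1) is unique.
    """
    if not R > Rc > 0:
        raise ValueError(f"phase 3 requires R > Rc > 0; got R={R}, Rc={Rc}")
    target = (Rc / R) ** 2

    def g(eta: float) -> float:
        return (1 - eta) ** 2 * (1 + 2 * eta) - target

    # g(0) = 1 - target > 0, g(1) = -target < 0
    return float(brentq(g, 0.0, 1.0, xtol=_ROOT_XTOL))


def solve_phi_phase3(R: float, eta: float, sp: StructuralParams) -> float:
    """Relative inhibited radius in phase 3, given the necrotic radius.

    The cubic g(φ) = R²φ³ + (Q²Rc² − R²(1+2η³))φ + 2η³R² changes sign on
    (η, 1): g(η) = η Rc² (Q² − 1) < 0 and g(1) = Q²Rc² > 0, bracketing one root.
    """
    Q, Rc = sp.Q, sp.Rc
    if not R > Rc:
        raise ValueError(f"phase 3 requires R > Rc; got R={R}, Rc={Rc}")
    lo, hi = eta, 1.0
    f_lo = _fs_phi(lo, eta, R, Q, Rc)
    f_hi = _fs_phi(hi, eta, R, Q, Rc)
    if not (f_lo < 0 < f_hi):
        raise RuntimeError(
            "phi bracket failed sign conditions: "
            f"g({lo:.6g})={f_lo:.6g}, g({hi:.6g})={f_hi:.6g} (inconsistent inputs?)"
        )
    return float(brentq(_fs_phi, lo, hi, args=(eta, R, Q, Rc), xtol=_ROOT_XTOL))


def structure_radius(R: float, sp: StructuralParams) -> Structure:
    """Inner structure as a function of outer radius.

    Phase 1 (R <= Q·Rc): no inhibited region, (phi, eta) = (0, 0).
    Phase 2 (Q·Rc < R <= Rc): phi = sqrt(1 − Q²Rc²/R²), eta = 0.
    Phase 3 (R > Rc): (phi, eta) solve the coupled cubic system.
    The map is continuous in R across both phase boundaries.
    """
    if R <= 0:
        raise ValueError(f"R must be positive; got {R}")
    Q, Rc = sp.Q, sp.Rc
    if R <= Q * Rc:
        return Structure(0.0, 0.0)
    if R <= Rc:
        phi2 = max(0.0, 1.0 - (Q * Rc / R) ** 2)
        return Structure(float(np.sqrt(phi2)), 0.0)
    eta = solve_eta_phase3(R, Rc)
    phi = solve_phi_phase3(R, eta, sp)
    return Structure(phi, eta)


def growth_rate(R: float, st: Structure, s: float, gamma: float) -> float:
    """Radial growth rate: rim proliferation minus necrotic mass loss (µm/d)."""
    if R <= 0:
        raise ValueError(f"R must be positive; got {R}")
    return (s / 3.0) * (1.0 - st.phi**3) * R - (s / 3.0) * gamma * st.eta**3 * R


def simulate_growth(
    R0: float,
    gp: GreenspanParams,
    s: float,
    t_grid: np.ndarray,
    rtol: float = 1e-8,
) -> Trajectory:
    """Integrate the growth ODE from R0 over t_grid (days).

    The structural map is re-solved at every right-hand-side evaluation; the
    trajectory passes the phase boundaries continuously.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if R0 <= 0:
        raise ValueError(f"R0 must be positive; got {R0}")
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    sp = gp.structural

    def rhs(t: float, y: np.ndarray) -> list[float]:
        st = structure_radius(float(y[0]), sp)
        return [growth_rate(float(y[0]), st, s, gp.gamma)]

    t0 = min(0.0, t_grid[0])
    sol = solve_ivp(
        rhs, (t0, t_grid[-1]), [R0], t_eval=t_grid, rtol=rtol, atol=1e-10,
        method="RK45",
    )
    if not sol.success:
        raise RuntimeError(f"growth integration failed: {sol.message}; last state {sol.y[:, -1]}")
    radii = sol.y[0]
    structures = [structure_radius(float(r), sp) for r in radii]
    return Trajectory(times=t_grid, radii=radii, structures=structures)


def _rho_equation(rho: float, Q: float, gamma: float) -> float:
    """Scalar steady-state residual in rho = etabar/phibar.

    Substituting phibar = (1 + gamma rho³)^(−1/3), etabar = rho·phibar into the
    structural system and eliminating Rbar leaves
    Q²(1−eta)²(1+2eta) = 1 − phi² − 2eta³(1−phi)/phi.
    """
    phi = (1.0 + gamma * rho**3) ** (-1.0 / 3.0)
    eta = rho * phi
    lhs = Q * Q * (1 - eta) ** 2 * (1 + 2 * eta)
    rhs = 1 - phi * phi - 2 * eta**3 * (1 - phi) / phi
    return lhs - rhs


def steady_state(gp: GreenspanParams, n_prescan: int = 1000) -> SteadyState:
    """Limiting structure m(theta) = (Rbar, phibar, etabar).

    Reduces the steady-state system to one scalar equation in
    rho = etabar/phibar on (0, 1), solved by bracketed root finding on the
    sign changes located by a pre-scan grid; the limiting radius follows in
    closed form, Rbar = Rc / ((1−etabar) sqrt(1+2 etabar)).
    """
    Q, Rc, gamma = gp.Q, gp.Rc, gp.gamma
    eps = 1e-12
    grid = np.linspace(eps, 1.0 - eps, n_prescan)
    vals = _rho_equation(grid, Q, gamma)  # vectorized
    sign_changes = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if len(sign_changes) == 0:
        raise NoSteadyStateError(
            f"no phase-3 steady state found for (Q={Q}, Rc={Rc}, gamma={gamma}): "
            "the rho equation has no sign change on (0, 1)"
        )
    roots = [
        float(brentq(_rho_equation, grid[i], grid[i + 1], args=(Q, gamma), xtol=_ROOT_XTOL))
        for i in sign_changes
    ]
    if len(roots) > 1:
        warnings.warn(
            f"multiple steady-state roots found: {roots}; taking the smallest",
            RuntimeWarning,
        )
    rho = min(roots)
    phi = (1.0 + gamma * rho**3) ** (-1.0 / 3.0)
    eta = rho * phi
    R_bar = Rc / ((1 - eta) * np.sqrt(1 + 2 * eta))
    if not R_bar > Rc:
        raise NoSteadyStateError(
            f"steady-state radius {R_bar:.6g} does not exceed Rc={Rc}: no phase-3 steady state"
        )
    return SteadyState(float(R_bar), float(phi), float(eta), float(rho))


def invert_steady_state(R_bar: float, phi_bar: float, eta_bar: float) -> GreenspanParams:
    """Closed-form inverse of the steady-state map.

    From the limiting triple: Rc = Rbar sqrt((1−eta)²(1+2eta));
    gamma = (1−phi³)/eta³; Q² = Rbar²[(1+2eta³)phi − phi³ − 2eta³]/(Rc² phi).
    Degenerate when eta = 0 (gamma is then unidentifiable).
    """
    if not (R_bar > 0 and 0 < eta_bar < phi_bar < 1):
        raise ValueError(
            f"inversion requires Rbar > 0 and 0 < eta < phi < 1; got "
            f"({R_bar}, {phi_bar}, {eta_bar})"
        )
    sp = invert_structure(R_bar, phi_bar, eta_bar)
    gamma = (1.0 - phi_bar**3) / eta_bar**3
    return GreenspanParams(sp.Q, sp.Rc, gamma)


def invert_structure(R: float, phi: float, eta: float) -> StructuralParams:
    """Closed-form (Q, Rc) from one phase-3 observation of (R, phi, eta)."""
    if not (R > 0 and 0 < eta < phi < 1):
        raise ValueError(
            f"inversion requires R > 0 and 0 < eta < phi < 1; got ({R}, {phi}, {eta})"
        )
    Rc = R * np.sqrt((1 - eta) ** 2 * (1 + 2 * eta))
    q2 = R * R * ((1 + 2 * eta**3) * phi - phi**3 - 2 * eta**3) / (Rc * Rc * phi)
    if not (0.0 < q2 < 1.0):
        raise ValueError(
            f"inverted Q² = {q2:.6g} outside (0, 1): observation is inconsistent "
            "with the phase-3 structural model"
        )
    return StructuralParams(float(np.sqrt(q2)), float(Rc))


def _steady_residuals(y: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Residuals of the full steady-state system F(y; theta) = 0."""
    R, phi, eta = y
    Q, Rc, gamma = theta
    return np.array(
        [
            1 - phi**3 - gamma * eta**3,
            _fs_eta(eta, R, Rc),
            _fs_phi(phi, eta, R, Q, Rc),
        ]
    )


def _steady_jacobians(y: np.ndarray, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Analytic partials of the steady residuals w.r.t. y = (R, phi, eta) and theta."""
    R, phi, eta = y
    Q, Rc, gamma = theta
    J_y = np.array(
        [
            [0.0, -3 * phi**2, -3 * gamma * eta**2],
            [2 * R * (2 * eta**3 - 3 * eta**2 + 1), 0.0, 6 * R * R * eta * (eta - 1)],
            [
                2 * R * (phi**3 - (1 + 2 * eta**3) * phi + 2 * eta**3),
                3 * R * R * phi**2 + Q * Q * Rc * Rc - R * R * (1 + 2 * eta**3),
                6 * eta**2 * R * R * (1 - phi),
            ],
        ]
    )
    J_theta = np.array(
        [
            [0.0, 0.0, -(eta**3)],
            [0.0, -2 * Rc, 0.0],
            [2 * Q * Rc * Rc * phi, 2 * Q * Q * Rc * phi, 0.0],
        ]
    )
    return J_y, J_theta


def jacobian_steady_state(gp: GreenspanParams) -> np.ndarray:
    """Sensitivity d(Rbar, phibar, etabar)/d(Q, Rc, gamma), 3x3.

    Implicit differentiation of the steady-state system with analytic
    partials: dy/dtheta = -J_y^{-1} J_theta.
    """
    ss = steady_state(gp)
    y = ss.as_array()
    theta = gp.as_array()
    J_y, J_theta = _steady_jacobians(y, theta)
    cond = np.linalg.cond(J_y)
    if cond > 1e12:
        raise RuntimeError(f"implicit system nearly singular (condition number {cond:.3g})")
    return -np.linalg.solve(J_y, J_theta)
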