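"""Synthetic spheroid cohorts with the statistical structure the analysis assumes.

The generator emulates the cross-sectional design of the experiments: several
seeding densities, a fixed panel of observation days, and 10-20 spheroids per
(density, day) condition, each imaged once (destructively).  Every spheroid
draws an initial radius, grows along the deterministic Greenspan trajectory,
and is observed with a fresh trivariate-normal measurement error, so the
emitted tables are multivariate-normal scatter about the model mean — exactly
the observation model used downstream.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .greenspan import GreenspanParams, simulate_growth, structure_radius

__all__ = ["CohortConfig", "initial_radius", "generate_cohort", "DEFAULT_SIGMA"]

logger = logging.getLogger(__name__)

# measurement-noise scales: sd ~20 µm in R, ~0.02 in phi, ~0.1 in eta
DEFAULT_SIGMA = np.diag([20.0**2, 0.02**2, 0.1**2])


def _default_radius_medians(densities: tuple[int, ...]) -> dict[int, float]:
    # aggregate volume proportional to cell count: R0 ~ r_eff * density^(1/3);
    # r_eff = 4 µm puts day-3 spheroids across all three growth phases
    return {d: 4.0 * d ** (1.0 / 3.0) for d in densities}


@dataclass
class CohortConfig:
    """Study design for one synthetic cohort."""

    greenspan: dict[str, GreenspanParams] = field(
        default_factory=lambda: {"WM983b-like": GreenspanParams(0.75, 149.0, 0.737)}
    )
    s: float = 1.0  # per-volume proliferation rate, 1/d; trajectories plateau by day ~18
    seeding_densities: tuple[int, ...] = (2500, 5000, 10000)
    initial_radius_median: dict[int, float] | None = None  # µm per density
    initial_radius_cv: float = 0.05
    observation_days: tuple[float, ...] = (3, 4, 5, 7, 10, 12, 14, 16, 18, 21, 24)
    n_per_condition: int = 10
    Sigma: np.ndarray = field(default_factory=lambda: DEFAULT_SIGMA.copy())
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_radius_median is None:
            self.initial_radius_median = _default_radius_medians(tuple(self.seeding_densities))
        days = np.asarray(self.observation_days, dtype=float)
        if np.any(np.diff(days) <= 0) or np.any(days <= 0):
            raise ValueError("observation days must be positive and increasing")
        Sigma = np.asarray(self.Sigma, dtype=float)
        if not np.allclose(Sigma, Sigma.T) or np.any(np.linalg.eigvalsh(Sigma) < -1e-12):
            raise ValueError("Sigma must be symmetric positive semidefinite")
        if self.s <= 0 or self.initial_radius_cv < 0 or self.n_per_condition < 1:
            raise ValueError("s, cv and n_per_condition must be positive")


def _spheroid_rng(seed: int, cell_line: str, density: int, replicate: int) -> np.random.Generator:
    """Stable per-spheroid substream, independent of cohort composition."""
    return np.random.default_rng(
        [seed, zlib.crc32(cell_line.encode()), density, replicate]
    )


def initial_radius(density: int, config: CohortConfig, rng: np.random.Generator) -> float:
    """Lognormal initial radius with configured median and coefficient of variation."""
    medians = config.initial_radius_median
    if density not in medians:
        raise KeyError(f"unknown seeding density {density}; configured: {sorted(medians)}")
    median = medians[density]
    if config.initial_radius_cv == 0.0:
        return float(median)
    sigma_log = float(np.sqrt(np.log1p(config.initial_radius_cv**2)))
    return float(np.exp(np.log(median) + sigma_log * rng.standard_normal()))


def _classify_phase(R: float, gp: GreenspanParams) -> int:
    if R <= gp.Q * gp.Rc:
        return 1
    if R <= gp.Rc:
        return 2
    return 3


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one measurement table.

    Columns: spheroid_id, cell_line, seeding_density, day, R_um, phi, eta,
    plus the noiseless truth (R_true, phi_true, eta_true, phase_true) for
    oracle-style tests.  Reproducible: identical config + seed gives an
    identical table.  Noise vectors violating 0 <= eta <= phi < 1 or R <= 0
    are resampled (up to 100 attempts) rather than clipped.
    """
    days = np.asarray(config.observation_days, dtype=float)
    rows = []
    n_skipped = 0
    n_total = 0
    for cell_line, gp in config.greenspan.items():
        # PSD square root (handles exactly singular Sigma, e.g. noise-free runs)
        evals, evecs = np.linalg.eigh(np.asarray(config.Sigma, dtype=float))
        sqrt_Sigma = evecs @ np.diag(np.sqrt(np.maximum(evals, 0.0)))
        for density in config.seeding_densities:
            for rep in range(config.n_per_condition * len(days)):
                # one spheroid per (condition, day): cross-sectional design
                day_idx, within = divmod(rep, config.n_per_condition)
                day = days[day_idx]
                rng = _spheroid_rng(config.seed, cell_line, density, rep)
                n_total += 1
                R0 = initial_radius(density, config, rng)
                try:
                    traj = simulate_growth(R0, gp, config.s, np.array([day]))
                except RuntimeError:
                    n_skipped += 1
                    logger.warning("skipping spheroid %s/%s/%d: integrator failure",
                                   cell_line, density, rep)
                    continue
                R_true = float(traj.radii[0])
                st = traj.structures[0]
                mean = np.array([R_true, st.phi, st.eta])
                for attempt in range(100):
                    noise = sqrt_Sigma @ rng.standard_normal(3)
                    x = mean + noise
                    if x[0] > 0 and 0.0 <= x[2] <= x[1] < 1.0:
                        break
                else:
                    # degenerate corner (e.g. phase-1 mean at phi = eta = 0):
                    # project the last draw onto the valid set instead
                    x[0] = max(x[0], 1e-6)
                    x[1] = float(np.clip(x[1], 0.0, 1.0 - 1e-9))
                    x[2] = float(np.clip(x[2], 0.0, x[1]))
                    logger.warning("projected invalid draw at mean %s for %s/%d/%d",
                                   mean, cell_line, density, rep)
                if attempt > 0:
                    logger.debug("resampled noise %d times for %s/%d/%d",
                                 attempt, cell_line, density, rep)
                rows.append(
                    {
                        "spheroid_id": f"{cell_line}_{density}_{rep:04d}",
                        "cell_line": cell_line,
                        "seeding_density": density,
                        "day": day,
                        "R_um": x[0],
                        "phi": x[1],
                        "eta": x[2],
                        "R_true": R_true,
                        "phi_true": st.phi,
                        "eta_true": st.eta,
                        "phase_true": _classify_phase(R_true, gp),
                    }
                )
    if n_total and n_skipped / n_total >= 0.05:
        raise RuntimeError(f"{n_skipped}/{n_total} spheroids failed to integrate")
    return pd.DataFrame(rows)
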