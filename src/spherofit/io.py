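"""Measurement-table I/O, analysis configuration, and the pipeline driver.

The canonical on-disk format is a flat CSV of per-spheroid morphometrics:

    spheroid_id,cell_line,seeding_density,day,R_um,phi,eta

Radii may alternatively be supplied as absolute `Ri_um`/`Rn_um` columns and
are converted to the dimensionless convention phi = Ri/R, eta = Rn/R on read.
All lengths are µm, all times days.  Reports are plain JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .greenspan import NoSteadyStateError, invert_steady_state
from .inference import (
    SteadyStateModel,
    MeanModel,
    lrt_group_equivalence,
    profile_parameter,
)
from .observation import SpheroidObservation, sample_moments, pooled_covariance
from .phase3 import fit_linear_tls, lrt_shared_trajectory, select_phase3, estimate_sigma_about_line

__all__ = [
    "SCHEMA_VERSION",
    "REQUIRED_COLUMNS",
    "AnalysisConfig",
    "read_measurements",
    "write_measurements",
    "table_to_observations",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
REQUIRED_COLUMNS = ["spheroid_id", "cell_line", "seeding_density", "day", "R_um", "phi", "eta"]


@dataclass
class AnalysisConfig:
    """Settings for one pipeline run."""

    alpha: float = 0.95
    model: str = "steady_state"  # statistical | steady_state | phase3_linear
    covariance_mode: str = "pooled"  # per_group | pooled
    steady_state_days: tuple[float, ...] | None = None  # None: last day per density
    group_by: tuple[str, ...] = ("seeding_density",)
    eta_min_phase3: float = 0.01
    profile: bool = True
    phase3: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1); got {self.alpha}")
        if self.model not in {"statistical", "structural", "steady_state", "phase3_linear"}:
            raise ValueError(f"unknown model {self.model!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def read_measurements(path: str | Path) -> pd.DataFrame:
    """Read and validate a measurement CSV.

    Absolute inner radii (Ri_um, Rn_um) are converted to phi/eta.  Rows that
    violate R > 0 or 0 <= eta <= phi <= 1, duplicate (spheroid_id, day) keys,
    or non-numeric fields are rejected with their row numbers.
    """
    df = pd.read_csv(path)
    if "phi" not in df.columns and "Ri_um" in df.columns:
        df["phi"] = df["Ri_um"] / df["R_um"]
    if "eta" not in df.columns and "Rn_um" in df.columns:
        df["eta"] = df["Rn_um"] / df["R_um"]
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    for col in ["seeding_density", "day", "R_um", "phi", "eta"]:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        coerced = pd.to_numeric(df[col], errors="coerce")
        nonnum = coerced.isna()
        if nonnum.any():
            row = int(np.nonzero(nonnum.to_numpy())[0][0])
            raise ValueError(f"non-numeric value in column {col!r} at row {row}")
        df[col] = coerced
    dup = df.duplicated(subset=["spheroid_id", "day"])
    if dup.any():
        rows = np.nonzero(dup.to_numpy())[0].tolist()
        raise ValueError(f"duplicate (spheroid_id, day) keys at rows {rows}")
    bad_R = df["R_um"] <= 0
    if bad_R.any():
        row = int(np.nonzero(bad_R.to_numpy())[0][0])
        raise ValueError(f"R_um must be positive: violation at row {row}")
    invalid = ~((0 <= df["eta"]) & (df["eta"] <= df["phi"]) & (df["phi"] <= 1))
    if invalid.any():
        row = int(np.nonzero(invalid.to_numpy())[0][0])
        raise ValueError(
            f"structure invariant 0 <= eta <= phi <= 1 violated at row {row}"
        )
    return df


def write_measurements(df: pd.DataFrame, path: str | Path, source: str = "unknown") -> None:
    """Write the canonical CSV plus a sidecar provenance JSON."""
    path = Path(path)
    out = df[[c for c in df.columns if c in REQUIRED_COLUMNS or c.endswith("_true")]]
    out.to_csv(path, index=False, float_format="%.10g")
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    prov = {
        "source": source,
        "schema_version": SCHEMA_VERSION,
        "package_version": __version__,
        "sha256": digest,
        "n_rows": int(len(df)),
    }
    path.with_suffix(".provenance.json").write_text(json.dumps(prov, indent=1))


def table_to_observations(df: pd.DataFrame) -> list[SpheroidObservation]:
    return [
        SpheroidObservation(
            spheroid_id=str(r.spheroid_id),
            cell_line=str(r.cell_line),
            seeding_density=int(r.seeding_density),
            day=float(r.day),
            R=float(r.R_um),
            phi=float(r.phi),
            eta=float(r.eta),
        )
        for r in df.itertuples()
    ]


def _steady_state_slice(df: pd.DataFrame, config: AnalysisConfig) -> dict[int, pd.DataFrame]:
    """Per-density late-day data used for steady-state analysis."""
    out = {}
    for density, sub in df.groupby("seeding_density"):
        if config.steady_state_days is not None:
            sel = sub[sub["day"].isin(config.steady_state_days)]
        else:
            sel = sub[sub["day"] == sub["day"].max()]
        out[int(density)] = sel
    return out


def run_pipeline(config: AnalysisConfig, table: pd.DataFrame) -> dict:
    """Run the full analysis on one measurement table; return a JSON-ready report.

    Stages: per-(density, day) moments; pooled covariance; per-density
    steady-state MLE with profile CIs; pairwise and joint group-equivalence
    tests; phase-3 TLS line fit with its equivalence test.
    """
    report: dict = {
        "package_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "n_rows": int(len(table)),
    }

    # --- per-condition moments -------------------------------------------
    moments = []
    groups = []
    for (density, day), sub in table.groupby(["seeding_density", "day"]):
        if len(sub) < 2:
            continue
        m = sample_moments(table_to_observations(sub), group_key=(int(density), float(day)))
        groups.append(m)
        moments.append(
            {"seeding_density": int(density), "day": float(day), "n": m.n,
             "mu": m.mu.tolist(), "Sigma": m.Sigma.tolist()}
        )
    report["moments"] = moments

    # --- steady-state analysis -------------------------------------------
    late = _steady_state_slice(table, config)
    late_moments = {
        d: sample_moments(table_to_observations(sub), group_key=d)
        for d, sub in late.items() if len(sub) >= 2
    }
    Sigma_pooled = pooled_covariance(list(late_moments.values()))
    report["pooled_covariance"] = Sigma_pooled.tolist()

    model = SteadyStateModel() if config.model != "statistical" else MeanModel()
    datasets = {}
    ss_section: dict = {}
    for density, m in late_moments.items():
        X = np.array([o.as_array() for o in table_to_observations(late[density])])
        Sigma = Sigma_pooled if config.covariance_mode == "pooled" else m.Sigma
        datasets[density] = [(X, Sigma)]
        fit = model.fit(datasets[density])
        entry = {"theta_hat": fit.theta_hat.tolist(), "loglik": fit.loglik_hat,
                 "n": int(len(X)), "mean": m.mu.tolist()}
        try:
            inv = invert_steady_state(*m.mu)
            entry["theta_from_mean_inversion"] = inv.as_array().tolist()
        except (ValueError, NoSteadyStateError):
            entry["theta_from_mean_inversion"] = None
        if config.profile and isinstance(model, SteadyStateModel):
            def obj(th, _ds=datasets[density]):
                return sum(model.loglik(th, d) for d in _ds)
            cis = []
            for i in range(3):
                prof = profile_parameter(obj, fit, i, model.bounds, alpha=config.alpha)
                cis.append(list(prof.ci))
            entry["profile_ci"] = cis
        ss_section[str(density)] = entry
    report["steady_state"] = ss_section

    # --- equivalence tests ------------------------------------------------
    tests: dict = {}
    keys = sorted(datasets)
    if len(keys) >= 2:
        joint = lrt_group_equivalence({k: datasets[k] for k in keys}, model)
        tests["all_groups"] = {"T": joint.T, "nu": joint.nu, "p": round(joint.p, 3)}
        for a, b in zip(keys[:-1], keys[1:]):
            r = lrt_group_equivalence({a: datasets[a], b: datasets[b]}, model)
            tests[f"{a}_vs_{b}"] = {"T": r.T, "nu": r.nu, "p": round(r.p, 3)}
    report["equivalence_tests"] = tests

    # --- phase-3 linear model ----------------------------------------------
    if config.phase3:
        obs_all = table_to_observations(table)
        try:
            p3 = select_phase3(obs_all, eta_min=config.eta_min_phase3)
        except ValueError:
            report["phase3"] = None
        else:
            X3 = np.array([o.as_array() for o in p3])
            Sigma3 = estimate_sigma_about_line(X3)
            line = fit_linear_tls(X3, Sigma3)
            p3_groups = {}
            for density in sorted({o.seeding_density for o in p3}):
                Xg = np.array([o.as_array() for o in p3 if o.seeding_density == density])
                if len(Xg) >= 3:
                    p3_groups[density] = Xg
            section = {
                "n": int(len(p3)),
                "anchor": line.anchor.tolist(),
                "direction": line.direction.tolist(),
                "per_group": {
                    str(d): {
                        "anchor": (f := fit_linear_tls(Xg, Sigma3)).anchor.tolist(),
                        "direction": f.direction.tolist(),
                        "n": int(len(Xg)),
                    }
                    for d, Xg in p3_groups.items()
                },
            }
            if len(p3_groups) >= 2:
                r = lrt_shared_trajectory(p3_groups, Sigma=Sigma3)
                section["equivalence_test"] = {"T": r.T, "nu": r.nu, "p": round(r.p, 3)}
            report["phase3"] = section

    return report
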