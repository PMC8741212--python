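#!/usr/bin/env python
"""Fit the empirical linear phase-3 trajectory and test its universality.

Selects observations with a measurable necrotic core (eta > 0.01), fits the
latent-progression line (R, phi, eta) = (Rc_emp, phi_c, 0) + tau q_hat by
total least squares under the pooled noise covariance, and tests whether one
line describes every seeding density.

Writes results/phase3.json and results/phase3_line.png.
"""

import argparse
import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

import spherofit as sf
from spherofit.io import read_measurements, table_to_observations
from spherofit.phase3 import estimate_sigma_about_line, fit_linear_tls

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
args = parser.parse_args()

table = read_measurements(args.cohort)
# the cohort's eta measurement noise has sd 0.1, so spurious small positives
# are common; select at twice that sd rather than the generic default
obs = sf.select_phase3(table_to_observations(table), eta_min=0.2)
X = np.array([o.as_array() for o in obs])
densities = np.array([o.seeding_density for o in obs])

Sigma = estimate_sigma_about_line(X)
line = fit_linear_tls(X, Sigma)
groups = {d: X[densities == d] for d in np.unique(densities) if (densities == d).sum() >= 3}
test = sf.lrt_shared_trajectory(groups, Sigma=Sigma)

out = {
    "n_phase3": int(len(X)),
    "anchor_Rc_phi": [round(float(v), 4) for v in line.anchor[:2]],
    "direction": [round(float(v), 5) for v in line.direction],
    "equivalence": {"T": round(test.T, 3), "nu": test.nu, "p": round(test.p, 3)},
}
Path("results").mkdir(exist_ok=True)
Path("results/phase3.json").write_text(json.dumps(out, indent=1))

tau_grid = np.linspace(line.tau.min(), line.tau.max(), 50)
pts = line.anchor + np.outer(tau_grid, line.direction)
fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
for ax, j, lbl in ((axes[0], 1, "phi"), (axes[1], 2, "eta")):
    for d in np.unique(densities):
        m = densities == d
        ax.plot(X[m, 0], X[m, j], ".", ms=4, alpha=0.6, label=f"{d} cells")
    ax.plot(pts[:, 0], pts[:, j], "k-", lw=2, label="TLS line")
    ax.set_xlabel("R (µm)")
    ax.set_ylabel(lbl)
axes[0].legend(fontsize=8)
fig.tight_layout()
fig.savefig("results/phase3_line.png", dpi=150)

print(f"phase-3 observations: {len(X)} of {len(table)}")
print(f"empirical necrosis onset: R ~ {line.anchor[0]:.0f} µm at phi_c ~ {line.anchor[1]:.3f}")
print(f"direction q_hat = {np.round(line.direction, 4)}")
print(f"shared-line test across densities: T={test.T:.3g}, nu={test.nu}, p={test.p:.3g}")
print("\nall densities share one generating trajectory, so the shared-line test "
      "should not reject strongly; note the generating structure-size relation "
      "is the curved Greenspan map, so a straight line is an approximation and "
      "its eta = 0 intercept underestimates the structural onset radius.")
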