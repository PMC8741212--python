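#!/usr/bin/env python
"""Likelihood inference on the synthetic cohort: MLEs, profile CIs, LRTs.

Runs the full pipeline on results/cohort.csv (generate it first with
01_simulate_cohort.py): per-condition moments, pooled covariance, per-density
steady-state MLEs with 95% profile-likelihood intervals, and likelihood-ratio
equivalence tests between seeding densities.

Writes results/report.json.
"""

import argparse
import json
from pathlib import Path

from spherofit.io import AnalysisConfig, read_measurements, run_pipeline

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--cohort", type=Path, default=Path("results/cohort.csv"))
args = parser.parse_args()

table = read_measurements(args.cohort)
config = AnalysisConfig(seed=args.seed)
report = run_pipeline(config, table)

Path("results/report.json").write_text(json.dumps(report, indent=1))

print("steady-state MLEs (last observation day per density), 95% profile CIs:")
for density, entry in report["steady_state"].items():
    q, rc, g = entry["theta_hat"]
    cis = entry.get("profile_ci")
    print(f"  {density:>6} cells: Q={q:.3f} Rc={rc:.1f} gamma={g:.3f}  (n={entry['n']})")
    if cis:
        for name, ci in zip(("Q", "Rc", "gamma"), cis):
            print(f"           {name}: ({ci[0]:.3g}, {ci[1]:.3g})")
print("\nequivalence tests (shared mechanistic parameters across densities):")
for key, t in report["equivalence_tests"].items():
    print(f"  {key}: T={t['T']:.3g}, nu={t['nu']}, p={t['p']:.3g}")
print("\nall densities were generated from one parameter set; rejections beyond "
      "the 5% chance level reflect residual growth at the last observation day "
      "(the steady-state model is exact only once growth has fully ceased, which "
      "also biases gamma upward slightly).")
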