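"""Uncertainty and validity diagnostics for per-gene rate estimates.

First draws bootstrap confidence bands for the rates of a noisy synthetic
gene (resampling cells with replacement), then runs the downsampling
analysis that asks which genes remain classifiable as cycling markers as
dropout increases.
"""

import numpy as np

from rnacycle.analysis import bootstrap_rates, downsample_validity, tpr_table
from rnacycle.kinetics import (
    PeriodicSpline,
    PhaseGrid,
    RateProfiles,
    simulate_mature_only,
    simulate_simplified_profiles,
)
from rnacycle.synthetic import marker_housekeeping_panel

grid = PhaseGrid(200, 19.33)
ph = grid.phases
rates = RateProfiles(
    grid,
    alpha=10.0 * (1.0 + 0.3 * np.sin(ph)),
    beta=np.full(200, 12.0),
    gamma=0.5 * (1.0 + 0.3 * np.sin(ph + 1.0)),
)
m = simulate_mature_only(rates.alpha, rates.gamma, grid)
mu, ml = simulate_simplified_profiles(rates, m, 1.0, grid)

rng = np.random.default_rng(5)
phases = rng.uniform(0, 2 * np.pi, 1000)
mu_c = rng.poisson(PeriodicSpline(ph, mu)(phases))
ml_c = rng.poisson(PeriodicSpline(ph, ml)(phases))

bands = bootstrap_rates(phases, mu_c, ml_c, 1.0, grid, B=100, seed=9)
for name, truth in (("gamma", rates.gamma), ("alpha", rates.alpha)):
    lo, hi = bands[f"{name}_bands"]
    cov = np.mean((truth >= lo) & (truth <= hi))
    width = np.mean(hi - lo)
    print(f"{name}: 90% band mean width {width:.3f}, covers truth at "
          f"{cov:.0%} of phases ({bands['n_failed']} failed replicates)")

print("\nDownsampling: marker recovery vs dropout (20 iterations/fraction)")
counts, phases_p, names, truth = marker_housekeeping_panel(400, seed=2)
val = downsample_validity(counts, phases_p, names,
                          fractions=(0.1, 0.3, 0.5, 0.8, 1.0), iters=20, seed=3)
print(tpr_table(val, truth).round(3).to_string(index=False))
print(
    "\nInterpretation: the bootstrap bands quantify cell-sampling noise in\n"
    "the rate profiles; the TPR column shows how marker classification\n"
    "degrades as counts are thinned, while flat housekeeping genes stay\n"
    "clean (FPR 0)."
)
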