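"""Three regulatory regimes producing one and the same expression profile.

Builds Case I (dynamic transcription, constant degradation), Case II
(constant transcription, dynamic degradation) and Case III (both dynamic)
for the shared mature-RNA target m(Φ) = 20 + 8·sin Φ, runs the periodic
forward simulation for each, and shows that the three simulated expression
profiles are indistinguishable even though the underlying kinetics differ.
"""

import numpy as np

from rnacycle.kinetics import PhaseGrid, simulate_total_profiles
from rnacycle.synthetic import SineTarget, three_case_scenarios

grid = PhaseGrid(n_points=500, period_hours=19.33)
target = SineTarget(mean=20.0, amplitude=8.0)
scenarios = three_case_scenarios(grid, target=target)

profiles = {}
for name, rates in scenarios.items():
    p, m, n_cycles = simulate_total_profiles(rates, grid, rel_tol=1e-6)
    profiles[name] = m
    err = np.max(np.abs(m - target.m(grid.phases)) / target.m(grid.phases))
    print(
        f"Case {name}: converged in {n_cycles} cycles; "
        f"max relative distance to target m(phi): {err:.2e}; "
        f"alpha range [{rates.alpha.min():.2f}, {rates.alpha.max():.2f}] /h, "
        f"gamma range [{rates.gamma.min():.3f}, {rates.gamma.max():.3f}] /h"
    )

pairs = [("I", "II"), ("I", "III"), ("II", "III")]
worst = max(
    np.max(np.abs(profiles[a] - profiles[b]) / profiles[b]) for a, b in pairs
)
print(f"\nlargest pairwise relative difference of the simulated m(phi): {worst:.2e}")
print(
    "Interpretation: the expression time course alone cannot distinguish the\n"
    "regimes - transcription amplitude, degradation amplitude, or both can\n"
    "produce it; only the labeled/unlabeled split resolves the kinetics."
)
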