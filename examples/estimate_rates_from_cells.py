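"""Phase-dependent rate estimation from a sampled single-cell experiment.

Generates the three-regime scenario plus flat background genes, samples
a noisy single-cell dataset (Poisson counts, lognormal capture), and runs
the per-gene analysis: smoothing, simplified-model rate estimation,
prediction deviations, peak calling, kinetic-mode classification and mean
half-lives.
"""

import pandas as pd

from rnacycle.analysis import analyze_counts
from rnacycle.io import RunConfig
from rnacycle.kinetics import PhaseGrid
from rnacycle.pipeline import simulate_scenario
from rnacycle.io import read_counts

cfg = RunConfig(output_dir="scratch/example_run", n_cells=800, grid_points=200,
                seed=11, labeling_time_hours=1.0)
out = simulate_scenario(cfg)
counts = read_counts(out / "counts")
print(f"sampled {len(counts.barcodes)} cells x {len(counts.genes)} genes")

summary, results = analyze_counts(counts, PhaseGrid(200, 19.33))
with pd.option_context("display.width", 120):
    print(summary[["gene", "is_cycling", "well_predicted", "dev",
                   "dev_c_alpha", "dev_c_gamma", "mode", "half_life_hours"]]
          .round(3).to_string(index=False))
print(
    "\nInterpretation: caseI-III cycle with a single expression peak and are\n"
    "assigned their planted kinetic mode (which rate had to vary to explain\n"
    "the data); the flat background genes are non-cycling with near-zero\n"
    "constant-rate deviations. Half-lives are ln(2)/mean(gamma) in hours."
)
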