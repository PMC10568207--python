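# rnacycle

Cell-cycle-resolved RNA kinetics from metabolic-labeling single-cell
RNA-seq.

Pulse-labeling cells with 4-thiouridine (4sU) marks newly synthesized RNA:
after chemical alkylation, incorporated 4sU reads as C instead of T, so
nascent transcripts carry diagnostic T→C conversions.  Combined with the
spliced/unspliced distinction, a single droplet-based scRNA-seq experiment
yields four RNA species per gene and cell — labeled/unlabeled ×
precursor/mature (pₗ, pᵤ, mₗ, mᵤ).  When cells are additionally ordered
along the cell cycle (a phase Φ ∈ [0, 2π) per cell), these four profiles
over-determine the three kinetic rates of the standard RNA life-cycle
model, making transcription α(Φ), splicing β(Φ) and degradation γ(Φ)
estimable **as functions of cell-cycle time, in absolute units**.

`rnacycle` implements the full computational path for this design:

1. **Read processing** — UMI-level merging of tagged reads with per-locus
   conversion evidence, SNP-position masking (mask a site if mismatch rate
   > 0.5 at depth ≥ 2 in an unlabeled control), splice-status calls.
2. **Labeling inference** — two-stage Bayesian classification.  Per locus,
   a binomial mixture separates true conversions from sequencing error:
   `pc = ρ·B(k; n, 1−εs) / [ρ·B(k; n, 1−εs) + (1−ρ)·B(k; n, εs)]`.
   Per molecule, a Poisson/binomial mixture separates new from old:
   `p_new = θ·Pois(k_m; n_m·ρₗ) / [θ·Pois(k_m; n_m·ρₗ) + (1−θ)·B(k_m; n_m, ε_c)]`,
   where `k_m` sums the locus posteriors and `n_m` counts the observed Ts.
   Posterior-weighted sums per gene/cell give the four count matrices.
3. **Kinetic model** — along the characteristics Φ(t) = Φ₀ + ωt
   (ω = 2π/T, cell-cycle period T = 19.33 h by default) the transport PDEs
   reduce to ODEs; the package integrates them (fixed-step RK4) for exact
   forward simulation, and inverts the short-labeling approximations for
   estimation.  Full model: `β = −(1/t)·log(pᵤ/p(Φ−ωt))`,
   `α = p(Φ−ωt)·β·pₗ/(p(Φ−ωt)−pᵤ)`, γ from a quadratic.  Simplified
   (precursor-free) model, used on sparse data:
   `γ̂ = −(1/t)·log(mᵤ/m(Φ−ωt))`, `α̂ = γ̂·m(Φ−ωt)·mₗ/(m(Φ−ωt)−mᵤ)`.
4. **Synthetic data** — for any target expression profile m(Φ), three
   regulatory regimes reproduce it exactly (Case I: dynamic α, constant γ;
   Case II: constant α, dynamic γ; Case III: both dynamic), plus samplers
   for single-cell count matrices and read-level tables with planted truth.
5. **Cycle analysis** — CPM normalization, cyclic penalized-spline
   smoothing (k = 20 basis, GCV with 1.4× EDF inflation), peak calling
   (peaking iff max/min ≥ 1.5; secondary peaks need prominence ≥ ¼ of the
   global range), prediction deviation `dev` (well-predicted iff ≤ 0.2),
   constant-rate deviations `dev_c` and kinetic-mode classes, mean
   half-lives t½ = ln 2/γ̄, bootstrap confidence bands, and a downsampling
   analysis of marker-call validity under dropout.

## Worked example

`python examples/simulate_three_regimes.py` builds the three regimes for
the shared target m(Φ) = 20 + 8·sin Φ and simulates each forward:

```
Case I: converged in 4 cycles; max relative distance to target m(phi): 1.41e-08; alpha range [5.23, 14.77] /h, gamma range [0.500, 0.500] /h
Case II: converged in 4 cycles; max relative distance to target m(phi): 1.16e-09; alpha range [10.00, 10.00] /h, gamma range [0.318, 0.872] /h
Case III: converged in 4 cycles; max relative distance to target m(phi): 1.69e-08; alpha range [2.48, 19.73] /h, gamma range [0.300, 0.700] /h

largest pairwise relative difference of the simulated m(phi): 1.69e-08
```

Three different kinetic programs produce numerically identical expression
profiles — expression alone cannot identify the kinetics.  Feeding sampled
noisy single-cell counts from these genes through the estimation pipeline
(`python examples/estimate_rates_from_cells.py`) recovers the regimes:

```
   gene  is_cycling  well_predicted   dev  dev_c_alpha  dev_c_gamma                  mode  half_life_hours
  caseI        True            True 0.043        0.294        0.026 dynamic transcription            1.519
 caseII        True            True 0.026        0.070        0.401   dynamic degradation            1.392
caseIII        True            True 0.086        0.787        0.302                  both            1.507
  flat0       False            True 0.006        0.042        0.036                 other            1.511
  flat1       False            True 0.006        0.038        0.049                 other            1.519
```

`dev` is the mean relative distance between rate-based predictions and the
observed smoothed profiles; `dev_c_alpha`/`dev_c_gamma` measure how much
the prediction moves when transcription/degradation is frozen at its cycle
mean — the pattern of which one exceeds 0.2 assigns the kinetic mode.

The other examples cover molecule-level labeling classification
(`classify_labeled_molecules.py`) and uncertainty/validity diagnostics
(`bootstrap_and_downsampling.py`).

A thin CLI wraps the same functions:

```sh
rnacycle simulate --out sim --n-cells 800 --seed 1
rnacycle analyze sim/counts --out analysis
rnacycle run --seed 1 --out full_run
```

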