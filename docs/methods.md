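# Methods

## Model

A cell's position in the cell cycle is a phase Φ ∈ [0, 2π), advanced at
constant angular velocity ω = 2π/T.  The default period T = 19.33 h is the
typical HEK293 cycle length; it is a configuration key
(`period_hours`), and all rates are reported per hour of real time.  Each
gene has three phase-dependent rates: transcription α(Φ) (expression units
per hour — counts, or CPM after normalization; conversion to absolute
molecules/cell would require a capture-efficiency factor that single-cell
data does not provide, so the package stays in input units), splicing
β(Φ) (1/h), degradation γ(Φ) (1/h).

During a 4sU pulse of length t, four species evolve along the
characteristic Φ(s) = Φ₀ + ωs:

    dpᵤ/ds = −β pᵤ              dpₗ/ds = α − β pₗ
    dmᵤ/ds = β pᵤ − γ mᵤ        dmₗ/ds = β pₗ − γ mₗ

with pᵤ = p(Φ₀), mᵤ = m(Φ₀), pₗ = mₗ = 0 at labeling onset, where p and m
are the periodic totals solving dp/dΦ = (α − βp)/ω, dm/dΦ = (βp − γm)/ω.
The model treats the population as a continuum over one cycle; molecule
halving at division is absorbed by the periodicity and not modeled
explicitly.

### Forward simulation

Both the periodic totals and the labeled species are integrated with
classical fixed-step 4th-order Runge–Kutta (deterministic, testable
tolerances).  The totals are iterated cycle over cycle from the
steady-state seed p₀ = α(0)/β(0), m₀ = α(0)/γ(0) until the maximum
relative cycle-to-cycle change of both profiles is below `rel_tol`
(default 10⁻⁶); for the default scenarios this takes ≤ 4 cycles.  The
integrator sub-steps automatically when the fastest rate would violate the
RK4 stability bound on a coarse grid (rate/ω · h kept ≤ 0.5).  Labeled
species are integrated in time from every grid phase and re-registered
onto the measurement grid by periodic cubic interpolation; conservation
pᵤ+pₗ = p and mᵤ+mₗ = m holds to ~10⁻⁷ relative and is asserted in tests.

### Inverse estimators

For labeling times much shorter than the period, the integrals over the
labeling window [Φ−ωt, Φ] are collapsed by the mean-value approximation,
giving closed-form inversions.

Full model: β(Φ) = −(1/t)·log(pᵤ/p(Φ−ωt)),
α(Φ) = p(Φ−ωt)·β·pₗ/(p(Φ−ωt)−pᵤ), and γ(Φ) as a root of

    γ² − β·(pₗ/mₗ + p₀/m₀ + 1)·γ
       + β²·(pₗ/mₗ)·(p₀/m₀)·((m₀−mᵤ)/(p₀−pᵤ) + 1) = 0

(p₀, m₀ denote the totals at labeling onset).  The constant term carries
the trailing "+1"; we verified on constant-rate closed forms that the root
then equals the true γ exactly.  Root selection: the root inside (0, β),
because degradation is slow compared with splicing in the regime where the
model applies; ties go to the smaller root, inadmissible points are filled
by periodic interpolation (or γ = 0 if no point is admissible, with a
warning).  In the β → 0 limit the α formula degenerates to 0/0 and is
replaced by its limit α = pₗ/t.

Simplified model (precursors dropped; appropriate when precursor counts
are an order of magnitude sparser than mature counts):
γ̂(Φ) = −(1/t)·log(mᵤ/m(Φ−ωt)) and α̂ = γ̂·m(Φ−ωt)·mₗ/(m(Φ−ωt)−mᵤ),
with the no-decay limit α̂ = mₗ/t engaged when mᵤ approaches m(Φ−ωt)
(relative depletion < 10⁻⁸) and γ̂ floored at 0 when noise pushes
mᵤ above the onset total.  Negative estimates anywhere are floored at 0
and counted.

Because these estimators invert the *approximated* solutions, applying
them to exact forward data returns labeling-window averages of the rates:
the bias is O(ωt) relative to the pointwise truth and vanishes as t → 0.
The package therefore ships two forward generators for the simplified
model — the approximated closed forms (`method="closed_form"`, which the
estimators invert exactly; used to validate the algebra) and the exact
characteristic ODE solutions (`method="characteristics"`, which carry the
window-average bias; used for self-consistency and pipeline tests).

### Predictions and deviations

Predicted mature profiles use the exact solutions of the precursor-free
system with the estimated rates, evaluated by trapezoidal quadrature on a
128-point sub-grid per labeling window with modular wrapping.  `dev` is
the mean relative distance between prediction and observation, maximized
over labeled, unlabeled and total mature; a gene is well-predicted iff
dev ≤ 0.2.  `dev_c` replaces one rate by its cycle constant (arithmetic
mean by default; median available via `constant_rate_statistic`), replaces
the total profile by the periodic solution of the modified system, and
measures the shift of the prediction.  The kinetic mode is read off which
`dev_c` exceeds the threshold (default 0.2, deliberately reusing the
well-predicted cutoff since both are the same deviation statistic; it is
configurable because no canonical value exists for the mode split).

## Synthetic data

The generator is regime-based: given any twice-differentiable positive
target m(Φ) (default: raised sine 20 + 8·sin Φ, amplitude chosen so all
derived rates stay positive) it constructs

* Case I:  α(Φ) = γm + ω(1+γ/β)m′ + (ω²/β)m″  (γ, β constant),
* Case II: γ(Φ) = [α + (βp₀−α)e^{−βΦ/ω}]/m − ωm′/m  (α, β constant;
  p₀ = α/β by default, which removes the non-periodic transient),
* Case III: α(Φ) = (γ + ωγ′/β)m + ω(1+γ/β)m′ + (ω²/β)m″ for a supplied
  differentiable γ(Φ),

so that all three regimes generate the *same* expression profile.
Defaults: β = 12/h (splicing in minutes), Case I γ = 0.5/h, Case II
α = 10/h, Case III γ = 0.5 + 0.2·sin(Φ+1).  Derivatives of built-in
targets are analytic; tabulated targets are differentiated spectrally
(exact for band-limited periodic profiles).

Single-cell sampling: phases uniform on [0, 2π) (an unsynchronized
population), counts Poisson with mean profile(Φ)·depth·capture, capture a
per-cell lognormal factor with unit mean and log-sd 0.3 by default.  This
noise model is the package's own choice; it reproduces the dominant
features of droplet data (shot noise, cell-to-cell depth variation) but
not zero inflation beyond Poisson, ambient RNA, doublets or batch
structure — passing tests therefore demonstrate correctness of the
estimators under sampling noise, not robustness to every real-data
artifact.  The end-to-end scenario adds flat constant-rate background
genes so that per-cell totals (and hence CPM) are not dominated by the
cycling genes themselves.

Read-level simulation: molecules draw their observed T count nm uniformly
from 10–150 (UMI-merged molecules expose tens to hundreds of Ts), new
molecules receive Poisson(nm·ρₗ) conversions (truncated at nm), old ones
Binomial(nm, ε_c) false positives; each molecule is fragmented into 1–5
overlapping reads that jointly cover its span, and each read/site
observation flips with probability εs.  Defaults ρₗ = 0.024, ε_c =
1.8·10⁻⁴, εs = 10⁻³.

## Labeling inference details

* ρ (sample conversion prior) = confident conversion loci (> 50% of
  covering reads converted) over total observed Ts, across all molecules;
  θ (per-gene new fraction) = fraction of molecules with ≥ 1 confident
  conversion locus.  Both computed after SNP masking, floored at 10⁻⁶ so
  an exact-zero prior cannot annihilate likelihood evidence.
* ρₗ is the pooled ratio Σ conversions/Σ Ts over precursor molecules of a
  saturation (24 h) labeling experiment; the per-molecule-mean variant is
  available but unstable for small nm.
* k_m (expected conversions per molecule) is a sum of posteriors, hence
  real-valued; it is rounded to the nearest integer for the pmf
  evaluations (pmfs live on integers); a Γ-continued Poisson variant is
  available via `continuous=True`.
* Mixture weights are normalized into proper posteriors.  At n = 0 both
  likelihoods are 1 and the posterior equals the prior.
* A (cell, UMI) pair mapped to two genes is dropped (conservative; no
  arbitration signal exists at this stage).  Molecules with only
  ambiguous exon/intron annotation are excluded from the count matrices.
* SNP masking removes conversion evidence at masked positions but keeps
  the reference T in n_m — the control only shows the site is unreliable
  for conversion calling, not that the T is absent.

## Smoothing and peak calling

Per-gene profiles against phase are smoothed with a cyclic P-spline: 20
periodic cubic B-splines on uniform knots over [0, 2π), circular
second-order difference penalty, penalty weight chosen by GCV on a log
grid with the effective degrees of freedom inflated by 1.4 (biasing
selection toward smoother fits).  Value and derivative are exactly
periodic across 0 ≡ 2π by basis construction.  At least 20 distinct
phases are required.

Peak calling evaluates the smooth on a 1000-point circular grid: a profile
peaks iff max/min ≥ 1.5 (values floored at 10⁻⁹·max before the ratio when
the minimum is non-positive); the global maximum is always a peak; any
other local maximum is a peak iff it exceeds the larger of its adjacent
local minima by ≥ ¼ of the global max−min.  Cycling = exactly one
expression peak.  Robust-cycling = well-predicted and neither rate profile
has more than one peak (the same peak rule is applied to rate profiles —
the natural extension, since both are smooth periodic profiles).

## Uncertainty and validity

Bootstrap: cells are resampled with replacement B times (default 100);
each replicate re-smooths and re-estimates; bands are pointwise 5–95%
quantiles.  All resampling flows through one seeded generator; identical
seeds give identical bands.  Replicates whose fit fails are dropped; more
than 20% failures abort.

Downsampling: the total-mature matrix is binomially thinned to fractions
0.1–1.0, `iters` times each; each replicate is CPM-normalized, smoothed
and classified by the fc ≥ 1.5 rule; a gene keeps its marker call iff
≥ 95% of replicates agree.  The dropout rate is the fraction of cells with
zero count after thinning.  TPR/FPR are tabulated against planted
marker/housekeeping truth.

## Validation scenarios and problem sizes

The acceptance tests fix these study conditions: 500-point grids for
estimator checks (200 points where a cheaper grid suffices); simplified
recovery on closed-form data with 30%-amplitude sinusoidal rates at
t = 1 h; full-model recovery on exact forward data with all three rates
sinusoidal (±20–30%) at t ∈ {0.5, 0.25, 0.1} h; round-trip prediction at
t = 0.05 h with 10%-amplitude rates — the short-labeling regime where the
window-average bias (linear in t) is far below the 10⁻³ consistency bound;
Poisson labeling statistics with 10,000 molecules at nm = 50; bootstrap
calibration with 1,000 cells at unit depth (mean mature counts ≈ 12–20
per cell, typical for well-expressed genes) where the Poisson sampling
noise dominates the smoothing bias; downsampling with 20 iterations per
fraction on a 400-cell panel.

## Known limitations

* Rates are expressed in input expression units; absolute molecules/min
  requires an external capture-efficiency calibration.
* The simplified estimators return labeling-window averages; at t = 1 h
  and rate amplitudes ≥ 30% the pointwise bias reaches a few percent.
* Labeling times beyond one cell-cycle period are not supported by the
  forward model.
* The direct discretized inverse problem (solving the linear system in
  the phase derivatives) is deliberately out of scope: it is numerically
  dominated by noise at realistic single-cell depths.
* Cell filtering, cell-cycle ordering and alignment are upstream of this
  package: it consumes tagged reads and/or count matrices with per-cell
  phases.
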