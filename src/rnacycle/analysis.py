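"""Per-gene cell-cycle statistics: peaks, deviations, modes, half-lives.

Downstream of the count matrices, every gene is reduced to smoothed
phase profiles of its mature species, simplified-model rate estimates, the
fidelity of the rate-based predictions (``dev``), the cost of freezing one
rate at its cycle mean (``dev_c``), a peak-count based cycling call, a
kinetic-mode class, a mean half-life, bootstrap confidence bands and a
dropout-based validity call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .kinetics import (
    TWO_PI,
    PhaseGrid,
    estimate_rates_simplified,
    predict_mature_profiles,
    predict_with_constant_rate,
)
from .smoothing import SmoothProfile, smooth_profile

logger = logging.getLogger(__name__)

WELL_PREDICTED_THRESHOLD = 0.2
FC_THRESHOLD = 1.5
PROMINENCE_FRACTION = 0.25

MODE_DYNAMIC_TRANSCRIPTION = "dynamic transcription"
MODE_DYNAMIC_DEGRADATION = "dynamic degradation"
MODE_BOTH = "both"
MODE_OTHER = "other"


# ---------------------------------------------------------------------------
# normalization


def normalize_cpm(counts, per_cell_totals=None):
    """Counts-per-million normalization.

    Divides each cell's column by its total captured molecules and scales
    by 1e6.  When ``per_cell_totals`` is omitted the matrix's own column
    sums are used (then columns sum to 1e6 exactly).  Cells with zero total
    are dropped, with a log entry; the returned matrix keeps the retained
    columns only, and the retained column indices are available via the
    second return value.
    """
    dense = not sparse.issparse(counts)
    mat = np.asarray(counts, dtype=float) if dense else counts.tocsc().astype(float)
    totals = (
        np.asarray(mat.sum(axis=0)).ravel()
        if per_cell_totals is None
        else np.asarray(per_cell_totals, dtype=float)
    )
    keep = totals > 0
    if not keep.all():
        logger.warning("dropping %d cells with zero total counts", int((~keep).sum()))
    mat = mat[:, keep]
    totals = totals[keep]
    scale = 1e6 / totals
    if dense:
        out = mat * scale[None, :]
    else:
        out = mat @ sparse.diags(scale)
    return out, np.flatnonzero(keep)


# ---------------------------------------------------------------------------
# peak calling


@dataclass
class PeakCall:
    is_peaking: bool
    n_peaks: int
    peak_phases: list = field(default_factory=list)
    fc_global: float = 1.0
    diff_global: float = 0.0


def _local_extrema(values: np.ndarray):
    """Circular local maxima/minima indices from sign changes of slope."""
    n = values.size
    diff = np.sign(np.diff(np.concatenate([values, values[:1]])))
    # collapse zero slopes to the previous non-zero sign so plateaus count once
    for i in range(n):
        if diff[i] == 0:
            diff[i] = diff[i - 1]
    maxima, minima = [], []
    for i in range(n):
        if diff[i - 1] > 0 and diff[i] < 0:
            maxima.append(i)
        elif diff[i - 1] < 0 and diff[i] > 0:
            minima.append(i)
    return maxima, minima


def find_peaks(
    profile,
    n_grid: int = 1000,
    fc_threshold: float = FC_THRESHOLD,
    prominence_fraction: float = PROMINENCE_FRACTION,
) -> PeakCall:
    """Peak call on a smooth periodic profile.

    A profile peaks iff its global fold change max/min is at least
    ``fc_threshold``.  The global maximum always counts as a peak; every
    other local maximum counts iff it rises above the larger of its two
    neighboring local minima by at least ``prominence_fraction`` of the
    global max-min difference.  Values are floored at a small positive
    epsilon before the ratio when the minimum is non-positive.

    ``profile`` is a :class:`SmoothProfile` (or any callable of phase);
    extrema are located on a dense circular grid.
    """
    phases = np.linspace(0.0, TWO_PI, n_grid, endpoint=False)
    values = np.asarray(profile(phases), dtype=float)
    vmax = float(values.max())
    vmin = float(values.min())
    diff_global = vmax - vmin
    floor = 1e-9 * max(abs(vmax), 1.0)
    if vmin <= 0:
        logger.warning("profile minimum <= 0; flooring for fold-change")
    fc_global = max(vmax, floor) / max(vmin, floor)
    if fc_global < fc_threshold or diff_global == 0:
        return PeakCall(False, 0, [], fc_global, diff_global)
    maxima, minima = _local_extrema(values)
    if not maxima:
        return PeakCall(False, 0, [], fc_global, diff_global)
    global_idx = max(maxima, key=lambda i: values[i])
    peaks = [global_idx]
    if minima:
        min_pos = np.array(sorted(minima))
        for idx in maxima:
            if idx == global_idx:
                continue
            # nearest local minima on either side, circularly
            right = min_pos[np.searchsorted(min_pos, idx) % len(min_pos)]
            left = min_pos[np.searchsorted(min_pos, idx) - 1]
            higher_min = max(values[left], values[right])
            if values[idx] - higher_min >= prominence_fraction * diff_global:
                peaks.append(idx)
    peak_phases = sorted(float(phases[i]) for i in peaks)
    return PeakCall(True, len(peaks), peak_phases, fc_global, diff_global)


def classify_cycling(peakcall: PeakCall) -> bool:
    """A gene cycles iff its expression profile has exactly one peak."""
    return bool(peakcall.is_peaking and peakcall.n_peaks == 1)


# ---------------------------------------------------------------------------
# deviations and modes


def deviation(pred, obs) -> float:
    """Mean absolute relative deviation of a prediction from an observation.

    ``dev = (1/m)·Σ |pred_i - obs_i| / obs_i``; points with ``obs_i = 0``
    are excluded (logged).  Scale-invariant under joint rescaling.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("pred and obs must have the same shape")
    ok = obs > 0
    if not ok.all():
        logger.warning("deviation: excluding %d points with obs <= 0", int((~ok).sum()))
    if not ok.any():
        raise ValueError("no positive observations")
    return float(np.mean(np.abs(pred[ok] - obs[ok]) / obs[ok]))


def max_deviation(pred_triplet, obs_triplet) -> float:
    """Per-gene dev: the maximum over labeled, unlabeled and total mature."""
    return max(deviation(p, o) for p, o in zip(pred_triplet, obs_triplet))


def classify_kinetic_mode(
    dev_c_alpha: float,
    dev_c_gamma: float,
    threshold: float = WELL_PREDICTED_THRESHOLD,
) -> str:
    """Kinetic-mode class from the two constant-rate deviations.

    A rate is "needed" dynamically when freezing it at its cycle constant
    moves the prediction by more than ``threshold``.
    """
    if dev_c_alpha < 0 or dev_c_gamma < 0:
        raise ValueError("deviations must be non-negative")
    a_dyn = dev_c_alpha > threshold
    g_dyn = dev_c_gamma > threshold
    if a_dyn and g_dyn:
        return MODE_BOTH
    if a_dyn:
        return MODE_DYNAMIC_TRANSCRIPTION
    if g_dyn:
        return MODE_DYNAMIC_DEGRADATION
    return MODE_OTHER


def mean_half_life(gamma_profile) -> float:
    """Mean RNA half-life ``t1/2 = ln 2 / γ̄`` (hours) from the cycle mean."""
    gamma_bar = float(np.mean(gamma_profile))
    if gamma_bar <= 0:
        return float("nan")
    return float(np.log(2.0) / gamma_bar)


# ---------------------------------------------------------------------------
# per-gene kinetics pipeline


@dataclass
class GeneKinetics:
    gene: str
    grid: PhaseGrid
    labeling_time: float
    mu_profile: np.ndarray
    ml_profile: np.ndarray
    m_profile: np.ndarray
    alpha_hat: np.ndarray
    gamma_hat: np.ndarray
    predictions: tuple
    dev: float
    dev_c_alpha: float
    dev_c_gamma: float
    expression_peaks: PeakCall
    alpha_peaks: PeakCall
    gamma_peaks: PeakCall
    is_cycling: bool
    well_predicted: bool
    robust_cycling: bool
    mode: str
    half_life_hours: float


def _profile_floor(values: np.ndarray) -> np.ndarray:
    floor = 1e-9 * max(float(np.max(values)), 1.0)
    return np.maximum(values, floor)


def estimate_gene_kinetics(
    gene: str,
    phases: np.ndarray,
    mu_cells: np.ndarray,
    ml_cells: np.ndarray,
    labeling_time: float,
    grid: PhaseGrid,
    mode_threshold: float = WELL_PREDICTED_THRESHOLD,
    constant_rate_statistic: str = "mean",
    k: int = 20,
) -> GeneKinetics:
    """Full simplified-model analysis of one gene from per-cell counts.

    Smooths the unlabeled, labeled and total mature expression against
    phase, estimates α̂(Φ) and γ̂(Φ), predicts the three mature profiles
    back from the rates, and derives dev, dev_c, peak calls, cycling/mode
    classifications and the mean half-life.
    """
    sm_mu = smooth_profile(mu_cells, phases, k=k)
    sm_ml = smooth_profile(ml_cells, phases, k=k)
    sm_m = smooth_profile(np.asarray(mu_cells) + np.asarray(ml_cells), phases, k=k)
    gp = grid.phases
    mu_prof = _profile_floor(sm_mu(gp))
    ml_prof = _profile_floor(sm_ml(gp))
    m_prof = _profile_floor(sm_m(gp))
    return analyze_gene_profiles(
        gene, mu_prof, ml_prof, m_prof, labeling_time, grid,
        expression_smooth=sm_m,
        mode_threshold=mode_threshold,
        constant_rate_statistic=constant_rate_statistic,
    )


def analyze_gene_profiles(
    gene: str,
    mu_prof: np.ndarray,
    ml_prof: np.ndarray,
    m_prof: np.ndarray,
    labeling_time: float,
    grid: PhaseGrid,
    expression_smooth=None,
    mode_threshold: float = WELL_PREDICTED_THRESHOLD,
    constant_rate_statistic: str = "mean",
) -> GeneKinetics:
    """Same as :func:`estimate_gene_kinetics` but from ready-made profiles."""
    alpha_hat, gamma_hat = estimate_rates_simplified(
        mu_prof, ml_prof, m_prof, labeling_time, grid
    )
    preds = predict_mature_profiles(alpha_hat, gamma_hat, m_prof, labeling_time, grid)
    obs = (ml_prof, mu_prof, m_prof)
    pred_triplet = (preds[1], preds[0], preds[2])
    dev = max_deviation(pred_triplet, obs)

    def const_dev(which):
        cpred = predict_with_constant_rate(
            alpha_hat, gamma_hat, m_prof, labeling_time, grid, which,
            statistic=constant_rate_statistic,
        )
        return max_deviation((cpred[1], cpred[0], cpred[2]), pred_triplet)

    dev_c_alpha = const_dev("transcription")
    dev_c_gamma = const_dev("degradation")
    expr_profile = expression_smooth or SmoothProfile.from_values(grid.phases, m_prof)
    expr_peaks = find_peaks(expr_profile)
    alpha_peaks = find_peaks(SmoothProfile.from_values(grid.phases, alpha_hat))
    gamma_peaks = find_peaks(SmoothProfile.from_values(grid.phases, gamma_hat))
    is_cycling = classify_cycling(expr_peaks)
    well_predicted = dev <= WELL_PREDICTED_THRESHOLD
    robust = bool(
        well_predicted and alpha_peaks.n_peaks <= 1 and gamma_peaks.n_peaks <= 1
    )
    return GeneKinetics(
        gene=gene,
        grid=grid,
        labeling_time=labeling_time,
        mu_profile=mu_prof,
        ml_profile=ml_prof,
        m_profile=m_prof,
        alpha_hat=alpha_hat,
        gamma_hat=gamma_hat,
        predictions=preds,
        dev=dev,
        dev_c_alpha=dev_c_alpha,
        dev_c_gamma=dev_c_gamma,
        expression_peaks=expr_peaks,
        alpha_peaks=alpha_peaks,
        gamma_peaks=gamma_peaks,
        is_cycling=is_cycling,
        well_predicted=well_predicted,
        robust_cycling=robust,
        mode=classify_kinetic_mode(dev_c_alpha, dev_c_gamma, mode_threshold),
        half_life_hours=mean_half_life(gamma_hat),
    )


def robust_cycling_filter(result: GeneKinetics) -> bool:
    """Well-predicted genes whose rate profiles are single-peaked."""
    return result.robust_cycling


def analyze_counts(
    counts,
    grid: PhaseGrid | None = None,
    mode_threshold: float = WELL_PREDICTED_THRESHOLD,
    constant_rate_statistic: str = "mean",
    normalize: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """Simplified-model kinetics for every gene of a LabeledCounts.

    CPM-normalizes against total captured molecules per cell, then runs
    :func:`estimate_gene_kinetics` per gene.  Returns a summary DataFrame
    and the per-gene :class:`GeneKinetics` objects.
    """
    grid = grid or PhaseGrid()
    phases = counts.cells["phase_radians"].to_numpy()
    t = float(counts.cells["labeling_time_hours"].iloc[0])
    mu = counts.mu.toarray().astype(float)
    ml = counts.ml.toarray().astype(float)
    if normalize:
        totals = counts.cell_totals()
        keep = totals > 0
        mu = mu[:, keep] * (1e6 / totals[keep])[None, :]
        ml = ml[:, keep] * (1e6 / totals[keep])[None, :]
        phases = phases[keep]
    rows = []
    results = {}
    for gi, gene in enumerate(counts.genes):
        try:
            res = estimate_gene_kinetics(
                gene, phases, mu[gi], ml[gi], t, grid,
                mode_threshold=mode_threshold,
                constant_rate_statistic=constant_rate_statistic,
            )
        except (ValueError, RuntimeError) as exc:
            logger.warning("gene %s skipped: %s", gene, exc)
            continue
        results[gene] = res
        rows.append(
            {
                "gene": gene,
                "is_cycling": res.is_cycling,
                "well_predicted": res.well_predicted,
                "robust_cycling": res.robust_cycling,
                "dev": res.dev,
                "dev_c_alpha": res.dev_c_alpha,
                "dev_c_gamma": res.dev_c_gamma,
                "mode": res.mode,
                "half_life_hours": res.half_life_hours,
                "n_peaks_expression": res.expression_peaks.n_peaks,
                "n_peaks_alpha": res.alpha_peaks.n_peaks,
                "n_peaks_gamma": res.gamma_peaks.n_peaks,
                "fc_global": res.expression_peaks.fc_global,
            }
        )
    return pd.DataFrame(rows), results


# ---------------------------------------------------------------------------
# bootstrap


def bootstrap_rates(
    phases: np.ndarray,
    mu_cells: np.ndarray,
    ml_cells: np.ndarray,
    labeling_time: float,
    grid: PhaseGrid,
    B: int = 100,
    q: tuple[float, float] = (0.05, 0.95),
    seed: int | np.random.Generator = 0,
    max_failed_fraction: float = 0.2,
) -> dict:
    """Pointwise rate confidence bands by resampling cells with replacement.

    Each of ``B`` replicates redraws cells, re-smooths and re-estimates
    α̂(Φ) and γ̂(Φ); the returned bands are the pointwise ``q`` quantiles
    (default 5-95%, a 90% interval).  Replicates whose fit fails are
    dropped and counted; more than ``max_failed_fraction`` failures raise.
    """
    if B < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    phases = np.asarray(phases, dtype=float)
    mu_cells = np.asarray(mu_cells, dtype=float)
    ml_cells = np.asarray(ml_cells, dtype=float)
    n = phases.size
    alphas, gammas = [], []
    n_failed = 0
    for _ in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            res = estimate_gene_kinetics(
                "boot", phases[idx], mu_cells[idx], ml_cells[idx],
                labeling_time, grid,
            )
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        alphas.append(res.alpha_hat)
        gammas.append(res.gamma_hat)
    if n_failed > max_failed_fraction * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed")
    alphas = np.array(alphas)
    gammas = np.array(gammas)
    point = estimate_gene_kinetics(
        "point", phases, mu_cells, ml_cells, labeling_time, grid
    )
    return {
        "alpha_bands": np.quantile(alphas, q, axis=0),
        "gamma_bands": np.quantile(gammas, q, axis=0),
        "alpha_hat": point.alpha_hat,
        "gamma_hat": point.gamma_hat,
        "n_failed": n_failed,
        "B": B,
    }


# ---------------------------------------------------------------------------
# downsampling validity


def binomial_thin(counts, fraction: float, rng: np.random.Generator):
    """Thin integer counts: each molecule survives independently w.p. fraction."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    arr = np.asarray(counts)
    if fraction == 1.0:
        return arr.copy()
    return rng.binomial(arr.astype(np.int64), fraction)


def downsample_validity(
    counts: np.ndarray,
    phases: np.ndarray,
    gene_names,
    fractions=(0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
    iters: int = 100,
    seed: int | np.random.Generator = 0,
    fc_threshold: float = FC_THRESHOLD,
    marker_quorum: float = 0.95,
    k: int = 20,
) -> pd.DataFrame:
    """Marker-gene classification stability under binomial downsampling.

    For every fraction, the total-mature count matrix is thinned ``iters``
    times; each replicate is CPM-normalized, smoothed and classified as
    marker iff its smoothed fold change reaches ``fc_threshold``.  A gene
    keeps its marker call at that fraction iff at least ``marker_quorum``
    of replicates classify it as marker.  The per-gene dropout rate is the
    fraction of cells with zero count after thinning.

    Returns a tidy frame with columns gene, fraction, dropout_rate,
    marker_rate, is_marker.
    """
    rng = np.random.default_rng(seed)
    counts = np.asarray(counts)
    if counts.ndim != 2:
        raise ValueError("counts must be genes x cells")
    rows = []
    for fraction in fractions:
        marker_hits = np.zeros(counts.shape[0])
        dropout = np.zeros(counts.shape[0])
        for _ in range(iters):
            thinned = binomial_thin(counts, fraction, rng)
            dropout += (thinned == 0).mean(axis=1)
            cpm, kept = normalize_cpm(thinned)
            ph = phases[kept]
            for gi in range(counts.shape[0]):
                try:
                    sm = smooth_profile(cpm[gi], ph, k=k)
                except (ValueError, RuntimeError):
                    continue
                call = find_peaks(sm, fc_threshold=fc_threshold)
                marker_hits[gi] += call.is_peaking
        marker_rate = marker_hits / iters
        dropout /= iters
        for gi, gene in enumerate(gene_names):
            rows.append(
                {
                    "gene": gene,
                    "fraction": fraction,
                    "dropout_rate": dropout[gi],
                    "marker_rate": marker_rate[gi],
                    "is_marker": marker_rate[gi] >= marker_quorum,
                }
            )
    return pd.DataFrame(rows)


def tpr_table(validity: pd.DataFrame, truth: dict[str, bool]) -> pd.DataFrame:
    """True-positive rate of marker recovery per downsampling fraction.

    ``truth`` maps gene name to whether the full-depth profile is a marker.
    TPR = TP/(TP+FN) among true markers; FPR likewise among true
    housekeeping genes.
    """
    out = []
    for fraction, grp in validity.groupby("fraction"):
        is_marker_true = grp["gene"].map(truth).to_numpy(dtype=bool)
        called = grp["is_marker"].to_numpy(dtype=bool)
        tp = int((called & is_marker_true).sum())
        fn = int((~called & is_marker_true).sum())
        fp = int((called & ~is_marker_true).sum())
        tn = int((~called & ~is_marker_true).sum())
        out.append(
            {
                "fraction": fraction,
                "mean_dropout_markers": grp.loc[is_marker_true, "dropout_rate"].mean(),
                "TP": tp,
                "FN": fn,
                "FP": fp,
                "TN": tn,
                "TPR": tp / (tp + fn) if tp + fn else float("nan"),
                "FPR": fp / (fp + tn) if fp + tn else float("nan"),
            }
        )
    return pd.DataFrame(out).sort_values("fraction").reset_index(drop=True)
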