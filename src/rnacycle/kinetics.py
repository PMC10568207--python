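"""Phase-dependent RNA kinetics: forward model and rate estimators.

The cell cycle is modeled as uniform motion on a circle: a cell at phase
``Φ ∈ [0, 2π)`` advances with constant angular velocity ``ω = 2π/T`` where
``T`` is the cell-cycle period in hours.  Each gene carries three
phase-dependent kinetic rates: transcription ``α(Φ)`` (expression units per
hour), splicing ``β(Φ)`` (1/h) and degradation ``γ(Φ)`` (1/h).  During a
metabolic-labeling experiment of duration ``t`` the four observable RNA
species are the unlabeled/labeled precursor (``pu``, ``pl``) and mature
(``mu``, ``ml``) amounts; unlabeled species can only decay or convert while
labeled species are fed by transcription.

Along the characteristic ``Φ(s) = Φ0 + ωs`` the transport PDEs for the four
species reduce to ODEs::

    dpu/ds = -β pu            dpl/ds = α - β pl
    dmu/ds =  β pu - γ mu     dml/ds = β pl - γ ml

with initial conditions ``pu = p(Φ0)``, ``mu = m(Φ0)``, ``pl = ml = 0`` where
``p`` and ``m`` are the periodic total profiles.  This module integrates
those ODEs (classical fixed-step RK4), and inverts the short-labeling
approximations of their solutions to estimate rates from observed profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

logger = logging.getLogger(__name__)

TWO_PI = 2.0 * np.pi


class PeriodicSpline:
    """Cubic interpolant of a periodic profile sampled on [0, 2π)."""

    def __init__(self, phases: np.ndarray, values: np.ndarray):
        phases = np.asarray(phases, dtype=float)
        values = np.asarray(values, dtype=float)
        if phases.ndim != 1 or phases.shape != values.shape:
            raise ValueError("phases and values must be matching 1-D arrays")
        x = np.append(phases, phases[0] + TWO_PI)
        y = np.append(values, values[0])
        self._spline = CubicSpline(x, y, bc_type="periodic")
        self._x0 = phases[0]

    def __call__(self, phi):
        return self._spline(self._x0 + np.mod(phi - self._x0, TWO_PI))

    def derivative(self, phi):
        return self._spline(self._x0 + np.mod(phi - self._x0, TWO_PI), 1)


@dataclass(frozen=True)
class PhaseGrid:
    """Uniform grid of ``n_points`` phases on [0, 2π) with period ``T`` hours."""

    n_points: int = 500
    period_hours: float = 19.33

    def __post_init__(self):
        if self.n_points < 8:
            raise ValueError("need at least 8 grid points")
        if self.period_hours <= 0:
            raise ValueError("period must be positive")

    @property
    def omega(self) -> float:
        """Angular velocity ω = 2π/T in rad/h."""
        return TWO_PI / self.period_hours

    @property
    def spacing(self) -> float:
        return TWO_PI / self.n_points

    @property
    def phases(self) -> np.ndarray:
        return np.arange(self.n_points) * self.spacing

    def hours(self) -> np.ndarray:
        """Phase expressed in hours since Φ = 0."""
        return self.phases / self.omega


def phase_shift(values: np.ndarray, grid: PhaseGrid, delta: float) -> np.ndarray:
    """Evaluate a periodic profile at ``Φ + delta`` for every grid phase.

    ``phase_shift(m, grid, -omega * t)`` yields ``m(Φ - ωt)``, the profile at
    labeling onset for cells measured at phase ``Φ``.
    """
    return PeriodicSpline(grid.phases, values)(grid.phases + delta)


@dataclass
class RateProfiles:
    """Kinetic rates on a phase grid: α (units/h), β (1/h), γ (1/h)."""

    grid: PhaseGrid
    alpha: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        n = self.grid.n_points
        for name in ("alpha", "beta", "gamma"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.ndim == 0:
                arr = np.full(n, float(arr))
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape ({n},)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            object.__setattr__(self, name, arr)

    def interpolants(self):
        ph = self.grid.phases
        return (
            PeriodicSpline(ph, self.alpha),
            PeriodicSpline(ph, self.beta),
            PeriodicSpline(ph, self.gamma),
        )


@dataclass
class ExpressionProfiles:
    """The four RNA species on a phase grid at a fixed labeling time (hours)."""

    grid: PhaseGrid
    labeling_time: float
    pu: np.ndarray
    mu: np.ndarray
    pl: np.ndarray
    ml: np.ndarray

    @property
    def p(self) -> np.ndarray:
        return self.pu + self.pl

    @property
    def m(self) -> np.ndarray:
        return self.mu + self.ml

    def initial_totals(self) -> tuple[np.ndarray, np.ndarray]:
        """Totals at labeling onset, ``p(Φ-ωt)`` and ``m(Φ-ωt)``."""
        delta = -self.grid.omega * self.labeling_time
        return (
            phase_shift(self.p, self.grid, delta),
            phase_shift(self.m, self.grid, delta),
        )


class ConvergenceError(RuntimeError):
    pass


def _rk4_cycle(p0, m0, alpha, beta, gamma, grid):
    """One cycle of RK4 for dp/dΦ=(α-βp)/ω, dm/dΦ=(βp-γm)/ω on the grid.

    ``alpha``/``beta``/``gamma`` are (rate_at_nodes, rate_at_halfsteps)
    pairs precomputed on the grid.  Returns the profiles at the grid nodes
    and the state at 2π.
    """
    n = grid.n_points
    h = grid.spacing
    w = grid.omega
    (a0, a_half), (b0, b_half), (g0, g_half) = alpha, beta, gamma
    a1 = np.roll(a0, -1)
    b1 = np.roll(b0, -1)
    g1 = np.roll(g0, -1)
    p = np.empty(n)
    m = np.empty(n)
    pc, mc = p0, m0
    for i in range(n):
        p[i], m[i] = pc, mc

        def fp(a, b, pv):
            return (a - b * pv) / w

        def fm(b, g, pv, mv):
            return (b * pv - g * mv) / w

        k1p = fp(a0[i], b0[i], pc)
        k1m = fm(b0[i], g0[i], pc, mc)
        k2p = fp(a_half[i], b_half[i], pc + 0.5 * h * k1p)
        k2m = fm(b_half[i], g_half[i], pc + 0.5 * h * k1p, mc + 0.5 * h * k1m)
        k3p = fp(a_half[i], b_half[i], pc + 0.5 * h * k2p)
        k3m = fm(b_half[i], g_half[i], pc + 0.5 * h * k2p, mc + 0.5 * h * k2m)
        k4p = fp(a1[i], b1[i], pc + h * k3p)
        k4m = fm(b1[i], g1[i], pc + h * k3p, mc + h * k3m)
        pc = pc + h * (k1p + 2 * k2p + 2 * k3p + k4p) / 6.0
        mc = mc + h * (k1m + 2 * k2m + 2 * k3m + k4m) / 6.0
    return p, m, pc, mc


def simulate_total_profiles(
    rates: RateProfiles,
    grid: PhaseGrid | None = None,
    rel_tol: float = 1e-6,
    max_cycles: int = 100,
):
    """Periodic total precursor/mature profiles for given rates.

    Integrates the total system cycle after cycle, seeding from the
    steady-state values ``p0 = α(0)/β(0)`` and ``m0 = α(0)/γ(0)``, until the
    maximum relative cycle-to-cycle change of both profiles falls below
    ``rel_tol``.  Returns ``(p, m, n_cycles)``.
    """
    grid = grid or rates.grid
    if rel_tol <= 0:
        raise ValueError("rel_tol must be positive")
    a_fn, b_fn, g_fn = rates.interpolants()
    # sub-step the integrator where the fastest rate makes the grid step
    # stiff (RK4 stability demands rate/ω · h well below ~2.8)
    fastest = max(float(np.max(rates.beta)), float(np.max(rates.gamma)), 1e-12)
    n_sub = max(1, int(np.ceil(fastest / grid.omega * grid.spacing / 0.5)))
    fine = PhaseGrid(grid.n_points * n_sub, grid.period_hours)
    half = fine.phases + 0.5 * fine.spacing
    a = (a_fn(fine.phases), a_fn(half))
    b = (b_fn(fine.phases), b_fn(half))
    g = (g_fn(fine.phases), g_fn(half))
    pc = rates.alpha[0] / rates.beta[0]
    mc = rates.alpha[0] / rates.gamma[0]
    p_prev = m_prev = None
    for cycle in range(1, max_cycles + 1):
        p, m, pc, mc = _rk4_cycle(pc, mc, a, b, g, fine)
        p, m = p[::n_sub], m[::n_sub]
        if p_prev is not None:
            res_p = np.max(np.abs(p - p_prev) / np.maximum(np.abs(p_prev), 1e-300))
            res_m = np.max(np.abs(m - m_prev) / np.maximum(np.abs(m_prev), 1e-300))
            if max(res_p, res_m) < rel_tol:
                return p, m, cycle
        else:
            # the first cycle already counts toward convergence when the
            # steady-state seed happens to be the periodic solution
            res_p = abs(pc - p[0]) / max(abs(p[0]), 1e-300)
            res_m = abs(mc - m[0]) / max(abs(m[0]), 1e-300)
            if max(res_p, res_m) < rel_tol:
                return p, m, cycle
        p_prev, m_prev = p, m
    raise ConvergenceError(
        f"periodic simulation did not converge within {max_cycles} cycles "
        f"(last residuals p={res_p:.3e}, m={res_m:.3e})"
    )


def simulate_mature_only(
    alpha: np.ndarray,
    gamma: np.ndarray,
    grid: PhaseGrid,
    rel_tol: float = 1e-9,
    max_cycles: int = 200,
) -> np.ndarray:
    """Periodic solution of the precursor-free system dm/dΦ = (α - γm)/ω."""
    # with β := γ, the precursor equation dp/dΦ = (α - βp)/ω of the coupled
    # integrator is exactly the mature-only equation
    a = np.broadcast_to(np.asarray(alpha, dtype=float), (grid.n_points,)).copy()
    g = np.broadcast_to(np.asarray(gamma, dtype=float), (grid.n_points,)).copy()
    rates = RateProfiles(grid, alpha=a, beta=np.maximum(g, 1e-12), gamma=np.maximum(g, 1e-12))
    p, _m, _ = simulate_total_profiles(rates, grid, rel_tol=rel_tol, max_cycles=max_cycles)
    return p


def _resample_to_grid(end_phases: np.ndarray, values: np.ndarray, grid: PhaseGrid) -> np.ndarray:
    """Interpolate values known at ``end_phases`` (mod 2π) back onto the grid."""
    x = np.mod(end_phases, TWO_PI)
    order = np.argsort(x)
    return PeriodicSpline(x[order], values[order])(grid.phases)


def simulate_labeled_profiles(
    rates: RateProfiles,
    p: np.ndarray,
    m: np.ndarray,
    t: float,
    grid: PhaseGrid | None = None,
    n_steps: int | None = None,
) -> ExpressionProfiles:
    """Exact four-species profiles at labeling time ``t`` (hours).

    Integrates the characteristic ODEs from every grid phase as labeling
    onset, then re-registers the endpoint values onto the measurement grid.
    Conservation ``pu + pl = p`` and ``mu + ml = m`` holds to integration
    tolerance.
    """
    grid = grid or rates.grid
    if t < 0:
        raise ValueError("labeling time must be non-negative")
    if t >= grid.period_hours:
        raise ValueError("labeling longer than one cell cycle is not supported")
    if t == 0:
        return ExpressionProfiles(grid, 0.0, pu=p.copy(), mu=m.copy(),
                                  pl=np.zeros_like(p), ml=np.zeros_like(m))
    w = grid.omega
    if n_steps is None:
        fastest = max(float(np.max(rates.beta)), float(np.max(rates.gamma)), 1e-12)
        n_steps = max(
            100,
            int(np.ceil(4 * w * t / grid.spacing)),
            int(np.ceil(fastest * t / 0.5)),  # stiffness guard
        )
    dt = t / n_steps
    a_fn, b_fn, g_fn = rates.interpolants()
    phi0 = grid.phases
    pu = np.array(p, dtype=float)
    mu = np.array(m, dtype=float)
    pl = np.zeros_like(pu)
    ml = np.zeros_like(mu)

    def deriv(s, state):
        phs = phi0 + w * s
        a = a_fn(phs)
        b = b_fn(phs)
        g = g_fn(phs)
        pu_, mu_, pl_, ml_ = state
        return (
            -b * pu_,
            b * pu_ - g * mu_,
            a - b * pl_,
            b * pl_ - g * ml_,
        )

    state = (pu, mu, pl, ml)
    for i in range(n_steps):
        s = i * dt
        k1 = deriv(s, state)
        k2 = deriv(s + 0.5 * dt, tuple(x + 0.5 * dt * k for x, k in zip(state, k1)))
        k3 = deriv(s + 0.5 * dt, tuple(x + 0.5 * dt * k for x, k in zip(state, k2)))
        k4 = deriv(s + dt, tuple(x + dt * k for x, k in zip(state, k3)))
        state = tuple(
            x + dt * (a1 + 2 * a2 + 2 * a3 + a4) / 6.0
            for x, a1, a2, a3, a4 in zip(state, k1, k2, k3, k4)
        )
    end = phi0 + w * t
    pu, mu, pl, ml = (_resample_to_grid(end, v, grid) for v in state)
    return ExpressionProfiles(grid, t, pu=pu, mu=mu, pl=pl, ml=ml)


def simulate_simplified_profiles(
    rates: RateProfiles,
    m: np.ndarray,
    t: float,
    grid: PhaseGrid | None = None,
    method: str = "closed_form",
) -> tuple[np.ndarray, np.ndarray]:
    """Mature labeled/unlabeled profiles under the precursor-free model.

    ``method="closed_form"`` evaluates the short-labeling approximations
    ``mu = m(Φ-ωt)·exp(-t·γ(Φ))`` and ``ml = (α/γ)(1-exp(-t·γ(Φ)))`` — the
    forms the simplified estimators invert exactly.  ``method=
    "characteristics"`` integrates the precursor-free ODEs exactly along the
    characteristics instead.  Returns ``(mu, ml)`` on the grid.
    """
    grid = grid or rates.grid
    if method == "closed_form":
        m0 = phase_shift(m, grid, -grid.omega * t)
        decay = np.exp(-t * rates.gamma)
        mu = m0 * decay
        with np.errstate(divide="ignore", invalid="ignore"):
            ml = np.where(
                rates.gamma > 0,
                rates.alpha / np.maximum(rates.gamma, 1e-300) * (1.0 - decay),
                rates.alpha * t,
            )
        return mu, ml
    if method == "characteristics":
        w = grid.omega
        n_steps = max(100, int(np.ceil(4 * w * t / grid.spacing)))
        dt = t / n_steps
        a_fn, _, g_fn = rates.interpolants()
        phi0 = grid.phases
        mu = np.array(m, dtype=float)
        ml = np.zeros_like(mu)

        def deriv(s, mu_, ml_):
            phs = phi0 + w * s
            a = a_fn(phs)
            g = g_fn(phs)
            return -g * mu_, a - g * ml_

        for i in range(n_steps):
            s = i * dt
            k1u, k1l = deriv(s, mu, ml)
            k2u, k2l = deriv(s + 0.5 * dt, mu + 0.5 * dt * k1u, ml + 0.5 * dt * k1l)
            k3u, k3l = deriv(s + 0.5 * dt, mu + 0.5 * dt * k2u, ml + 0.5 * dt * k2l)
            k4u, k4l = deriv(s + dt, mu + dt * k3u, ml + dt * k3l)
            mu = mu + dt * (k1u + 2 * k2u + 2 * k3u + k4u) / 6.0
            ml = ml + dt * (k1l + 2 * k2l + 2 * k3l + k4l) / 6.0
        end = phi0 + w * t
        return _resample_to_grid(end, mu, grid), _resample_to_grid(end, ml, grid)
    raise ValueError(f"unknown method {method!r}")


def _fill_invalid(
    values: np.ndarray, invalid: np.ndarray, what: str, fallback: float | None = None
) -> np.ndarray:
    """Replace flagged grid points by periodic linear interpolation."""
    if not invalid.any():
        return values
    if invalid.all():
        if fallback is not None:
            logger.warning("%s: no valid grid point, falling back to %g", what, fallback)
            return np.full_like(values, fallback)
        raise ValueError(f"all grid points invalid while estimating {what}")
    n = values.size
    logger.warning("%s: interpolating %d invalid grid points", what, int(invalid.sum()))
    idx = np.arange(n)
    good = idx[~invalid]
    # periodic linear interpolation on the index circle
    ext_idx = np.concatenate([good, good + n])
    ext_val = np.concatenate([values[good], values[good]])
    out = values.copy()
    out[invalid] = np.interp(idx[invalid] + n, ext_idx, ext_val)
    return out


def solve_gamma_quadratic(
    profiles: ExpressionProfiles,
    beta: np.ndarray,
    t: float | None = None,
    grid: PhaseGrid | None = None,
) -> np.ndarray:
    """Degradation rate from the full-model quadratic.

    Per grid point solves ``γ² − β·(pl/ml + p0/m0 + 1)·γ +
    β²·(pl/ml)·(p0/m0)·((m0−mu)/(p0−pu) + 1) = 0`` with ``p0, m0`` the
    totals at labeling onset, and returns the root in ``(0, β)`` (degradation
    is slow compared with splicing); points with a negative discriminant or
    no admissible root are filled by periodic interpolation.
    """
    grid = grid or profiles.grid
    p0, m0 = profiles.initial_totals()
    pl, ml = profiles.pl, profiles.ml
    pu, mu = profiles.pu, profiles.mu
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_p = pl / ml
        ratio_0 = p0 / m0
        tail = (m0 - mu) / (p0 - pu) + 1.0
        b_coef = beta * (ratio_p + ratio_0 + 1.0)
        c_coef = beta**2 * ratio_p * ratio_0 * tail
        disc = b_coef**2 - 4.0 * c_coef
    invalid = ~np.isfinite(disc) | (disc < 0)
    disc_safe = np.where(invalid, 0.0, disc)
    sq = np.sqrt(disc_safe)
    root_small = (b_coef - sq) / 2.0
    root_large = (b_coef + sq) / 2.0
    # prefer the root inside (0, β); ties broken toward the smaller root
    gamma = np.where((root_small > 0) & (root_small < beta), root_small, root_large)
    invalid |= ~np.isfinite(gamma) | (gamma <= 0) | (gamma >= beta)
    gamma = np.where(invalid, np.nan, gamma)
    return _fill_invalid(
        np.nan_to_num(gamma, nan=0.0), invalid, "gamma quadratic", fallback=0.0
    )


def estimate_rates_full(
    profiles: ExpressionProfiles,
    t: float | None = None,
    grid: PhaseGrid | None = None,
) -> RateProfiles:
    """Full-model rate estimates from four observed profiles.

    Short-labeling inversions: ``β = -(1/t)·log(pu/p(Φ-ωt))``,
    ``α = p(Φ-ωt)·β·pl/(p(Φ-ωt)-pu)`` and γ from the quadratic.  Valid for
    labeling times much shorter than the period; estimates are clamped at 0
    from below (count recorded in ``flags["n_clamped"]``).
    """
    grid = grid or profiles.grid
    t = profiles.labeling_time if t is None else t
    if t <= 0:
        raise ValueError("labeling time must be positive")
    p0, m0 = profiles.initial_totals()
    pu, pl = profiles.pu, profiles.pl
    if np.any(p0 <= 0) or np.any(pu <= 0):
        raise ValueError("full-model estimation requires positive precursor profiles")
    beta = -np.log(pu / p0) / t
    denom = p0 - pu
    bad = np.abs(denom) < 1e-9 * np.maximum(p0, 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = p0 * beta * pl / denom
    # β → 0 limit: p0 - pu → p0·β·t and pl → α·t, hence α → pl/t
    alpha = np.where(bad, pl / t, alpha)
    alpha = _fill_invalid(np.nan_to_num(alpha), ~np.isfinite(alpha), "alpha (full)")
    gamma = solve_gamma_quadratic(profiles, beta, t, grid)
    n_clamped = int(np.sum(alpha < 0) + np.sum(beta < 0) + np.sum(gamma < 0))
    if n_clamped:
        logger.warning("clamped %d negative rate values to 0", n_clamped)
    return RateProfiles(
        grid,
        alpha=np.maximum(alpha, 0.0),
        beta=np.maximum(beta, 0.0),
        gamma=np.maximum(gamma, 0.0),
        flags={"n_clamped": n_clamped},
    )


def estimate_rates_simplified(
    mu: np.ndarray,
    ml: np.ndarray,
    m: np.ndarray,
    t: float,
    grid: PhaseGrid,
) -> tuple[np.ndarray, np.ndarray]:
    """Simplified-model (precursor-free) rate estimates.

    ``γ̂(Φ) = -(1/t)·log(mu(Φ,t)/m(Φ-ωt))`` and
    ``α̂(Φ) = γ̂·m(Φ-ωt)·ml/(m(Φ-ωt)-mu)``; in the no-decay limit
    ``mu → m(Φ-ωt)`` the transcription estimate tends to ``ml/t``.
    Returns ``(alpha_hat, gamma_hat)``; noise-induced negative values are
    floored at 0.
    """
    if t <= 0:
        raise ValueError("labeling time must be positive")
    m0 = phase_shift(np.asarray(m, dtype=float), grid, -grid.omega * t)
    if np.any(m0 <= 0):
        raise ValueError("total mature profile must be positive at labeling onset")
    ratio = np.asarray(mu, dtype=float) / m0
    over = ratio >= 1.0  # noise: more unlabeled than total at onset
    ratio_c = np.clip(ratio, 1e-300, 1.0)
    gamma_hat = -np.log(ratio_c) / t
    gamma_hat[over] = 0.0
    depletion = m0 - mu
    small = np.abs(depletion) < 1e-8 * m0
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = gamma_hat * m0 * ml / depletion
    alpha_hat = np.where(small | over, np.asarray(ml, dtype=float) / t, alpha_hat)
    alpha_hat = np.maximum(np.nan_to_num(alpha_hat), 0.0)
    return alpha_hat, gamma_hat


def predict_mature_profiles(
    alpha_hat: np.ndarray,
    gamma_hat: np.ndarray,
    m: np.ndarray,
    t: float,
    grid: PhaseGrid,
    n_sub: int = 128,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predicted mature profiles from estimated rates.

    Exact solutions of the precursor-free system evaluated by trapezoidal
    quadrature over the labeling window with modular wrapping::

        m̂u(Φ,t) = m(Φ-ωt)·exp(-(1/ω)∫_{Φ-ωt}^{Φ} γ̂)
        m̂l(Φ,t) = (1/ω)∫_{Φ-ωt}^{Φ} α̂(φ)·exp(-(1/ω)∫_{φ}^{Φ} γ̂) dφ

    Returns ``(mu_pred, ml_pred, m_pred)``.
    """
    w = grid.omega
    a_fn = PeriodicSpline(grid.phases, np.asarray(alpha_hat, dtype=float))
    g_fn = PeriodicSpline(grid.phases, np.asarray(gamma_hat, dtype=float))
    m0 = phase_shift(np.asarray(m, dtype=float), grid, -w * t)
    if t == 0:
        return m0.copy(), np.zeros_like(m0), m0.copy()
    # sub-grid over the labeling window for every measurement phase
    offsets = np.linspace(-w * t, 0.0, n_sub + 1)
    phi = grid.phases[:, None] + offsets[None, :]
    dphi = w * t / n_sub
    a_vals = a_fn(phi)
    g_vals = g_fn(phi)
    # G[i, j] = ∫_{φ_ij}^{Φ_i} γ̂  (reverse cumulative trapezoid)
    seg = 0.5 * (g_vals[:, 1:] + g_vals[:, :-1]) * dphi
    G = np.concatenate(
        [np.cumsum(seg[:, ::-1], axis=1)[:, ::-1], np.zeros((grid.n_points, 1))], axis=1
    )
    mu_pred = m0 * np.exp(-G[:, 0] / w)
    integrand = a_vals * np.exp(-G / w)
    ml_pred = np.trapezoid(integrand, dx=dphi, axis=1) / w
    return mu_pred, ml_pred, mu_pred + ml_pred


def predict_with_constant_rate(
    alpha_hat: np.ndarray,
    gamma_hat: np.ndarray,
    m: np.ndarray,
    t: float,
    grid: PhaseGrid,
    which: str,
    statistic: str = "mean",
    n_sub: int = 128,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Predictions with one rate replaced by its cycle-constant value.

    ``which`` selects the rate held constant ("transcription" or
    "degradation"); ``statistic`` is the cycle summary used ("mean" or
    "median").  The total mature profile is replaced by the periodic
    solution of the modified precursor-free system before predicting, so a
    rate that already was constant reproduces the dynamic prediction.
    """
    reducer = {"mean": np.mean, "median": np.median}[statistic]
    alpha_hat = np.asarray(alpha_hat, dtype=float)
    gamma_hat = np.asarray(gamma_hat, dtype=float)
    if which == "transcription":
        alpha_c = np.full_like(alpha_hat, reducer(alpha_hat))
        gamma_c = gamma_hat
    elif which == "degradation":
        alpha_c = alpha_hat
        gamma_c = np.full_like(gamma_hat, reducer(gamma_hat))
    else:
        raise ValueError("which must be 'transcription' or 'degradation'")
    m_const = simulate_mature_only(alpha_c, np.maximum(gamma_c, 1e-9), grid)
    return predict_mature_profiles(alpha_c, gamma_c, m_const, t, grid, n_sub=n_sub)
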