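"""Predator-prey analysis of the ecosystem under E. coli lysis.

Adding a first-order *E. coli* degradation channel (rate ``d``) turns the
mutualism into an antagonistic loop: bacteria feed yeast resistance, yeast
feed bacterial resistance, and lysis removes bacteria.  As ``d`` increases
the coexistence fixed point loses stability through a Hopf bifurcation,
producing sustained population oscillations, and at still larger ``d`` the
system collapses.  This module finds the fixed points, their Jacobian
eigenvalues, the Hopf onset, the oscillation amplitude/period along the
``d`` axis, and the noise amplitude beyond which stochasticity destroys the
oscillations.  The bifurcation analysis runs on the deterministic part of
the equations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, signal

from .ensemble import run_ensemble, survival_fraction
from .integrate import IntegratorConfig, simulate
from .network import N_SPECIES, Parameters, drift, initial_state, propensities
from .phenotypes import SearchError

__all__ = [
    "find_fixed_point",
    "jacobian",
    "BifurcationResult",
    "scan_bifurcation",
    "oscillation_period",
    "autocorrelation_period",
    "NoiseScanResult",
    "noise_extinction_scan",
]

def _turnover(state: np.ndarray, params: Parameters) -> np.ndarray:
    """Per-species total flux sum_j |nu_ij| a_j, used to normalize residuals."""
    from .network import STOICHIOMETRY

    return np.abs(STOICHIOMETRY) @ propensities(state, params)


def _molecular_equilibrium(c1: float, c2: float, p: Parameters) -> np.ndarray:
    """Exact steady state of the seven molecular species for fixed populations.

    The signal pools obey a quadratic balance (linear decay plus pairwise
    binding); every downstream species then follows in closed form.
    """
    y = np.zeros(N_SPECIES)
    y[0], y[1] = c1, c2

    def signal(production, k_dec, k_bind, omega):
        # production = k_dec*A + 2*k_bind*A^2/omega, positive root
        b = 2.0 * k_bind / omega
        if b == 0:
            return production / k_dec if k_dec > 0 else 0.0
        return (-k_dec + np.sqrt(k_dec**2 + 4 * b * production)) / (2 * b)

    a2 = signal(p.k5 * c2, p.k12, p.k6_eff, p.omega1)   # AHL2 pool
    a1 = signal(p.k4 * c1, p.k11, p.k9_eff, p.omega2)   # AHL1 pool
    y[3], y[2] = a2, a1
    y[5] = p.k6_eff * a2**2 / p.omega1 / p.k14          # C2
    y[4] = p.k9_eff * a1**2 / p.omega2 / p.k13          # C1
    x = y[5] / p.omega1
    rate8 = p.omega1 * p.k7 * x**p.n1 / (p.k7b**p.n1 + x**p.n1) if x > 0 else 0.0
    y[6] = rate8 / p.k8                                  # preRes1
    y[7] = rate8 / p.k15                                 # Res1
    z = y[4] / p.omega2
    rate11 = p.omega2 * p.k10 * z**p.n2 / (p.k10b**p.n2 + z**p.n2) if z > 0 else 0.0
    y[8] = rate11 / p.k16                                # Res2
    return y


def _interior_fixed_point(params: Parameters, guess: np.ndarray,
                          tol: float) -> np.ndarray:
    """Coexistence fixed point via reduction to the population plane.

    With the molecular species at their exact conditional equilibria, the
    remaining conditions are the per-capita balances F1 = k1*L - killing1
    and F2 = k2*L - killing2 - d.  F2 is strictly decreasing in c2, so c2
    is bracketed by bisection for each c1; the outer condition F1 is then
    a 1-D root in log c1.  This stays well-posed even where the logistic
    direction makes the full 9-D (or 2-D Newton) problem near-singular.
    """
    p = params

    def F2(c1, c2):
        y = _molecular_equilibrium(c1, c2, p)
        L = 1.0 - (c1 + c2) / p.cmax
        return p.k2 * L - p.k3_eff / (1.0 + p.alpha2 * y[8]) - p.d

    def c2_given_c1(c1):
        lo, hi = 1.0, 2.0 * p.cmax
        if F2(c1, lo) <= 0 or F2(c1, hi) >= 0:
            return None
        return optimize.brentq(lambda c2: F2(c1, c2), lo, hi,
                               xtol=1e-9, rtol=8.9e-16)

    def F1(log_c1):
        c1 = 10.0 ** log_c1
        c2 = c2_given_c1(c1)
        if c2 is None:
            return None
        y = _molecular_equilibrium(c1, c2, p)
        L = 1.0 - (c1 + c2) / p.cmax
        return p.k1 * L - p.k3_eff / (1.0 + p.alpha1 * y[7])

    grid = np.linspace(0.0, 10.0, 51)  # c1 from 1 to 1e10 cells
    vals = [F1(g) for g in grid]
    bracket = None
    for i in range(len(grid) - 1):
        ga, va = grid[i], vals[i]
        gb, vb = grid[i + 1], vals[i + 1]
        if va is None:
            continue
        if va == 0.0:
            bracket = (ga, ga)
            break
        if vb is not None:
            if va * vb < 0:
                bracket = (ga, gb)
                break
        else:
            # the bacterial balance loses its root past some c1 (total
            # population pinned at capacity); the yeast balance plunges
            # negative just inside that edge, so refine toward it
            lo, hi, flo = ga, gb, va
            for _ in range(100):
                mid = 0.5 * (lo + hi)
                fm = F1(mid)
                if fm is None:
                    hi = mid
                elif flo * fm < 0:
                    bracket = (lo, mid)
                    break
                else:
                    lo, flo = mid, fm
                if hi - lo < 1e-12:
                    break
            if bracket is not None:
                break
    if bracket is None:
        raise SearchError("no interior fixed point: the per-capita yeast "
                          "balance has no sign change over c1 in [1, 1e10]")
    root_log_c1 = (bracket[0] if bracket[0] == bracket[1]
                   else optimize.brentq(F1, *bracket, xtol=1e-13))
    c1 = 10.0 ** root_log_c1
    c2 = c2_given_c1(c1)
    y = _molecular_equilibrium(c1, c2, p)
    L = 1.0 - (c1 + c2) / p.cmax
    res = max(abs(p.k1 * L - p.k3_eff / (1.0 + p.alpha1 * y[7])),
              abs(F2(c1, c2)))
    if res > tol:
        raise SearchError(f"interior fixed point residual {res:.3g}/h "
                          f"exceeds tolerance {tol:g}/h")
    return y


def find_fixed_point(
    params: Parameters,
    initial_guess: np.ndarray,
    tol: float = 1e-8,
) -> np.ndarray:
    """Solve drift(y) = 0 from a nonnegative guess.

    An interior guess (both populations positive) is first resolved through
    the population-plane reduction, which is exact and immune to the
    near-singular logistic direction; otherwise, and as a fallback, the
    full system is solved in log space with residuals normalized by each
    species' turnover flux.  Convergence requires the normalized residual
    to stay below ``tol``.
    """
    guess = np.asarray(initial_guess, dtype=np.float64)
    if np.any(guess < 0) or guess.shape != (N_SPECIES,):
        raise ValueError("initial guess must be a nonnegative 9-vector")

    def norm_residual(y):
        f = drift(y, params)
        return np.max(np.abs(f) / np.maximum(_turnover(y, params), 1e-30))

    if norm_residual(guess) <= tol:  # already a root (e.g. the origin)
        return guess

    if guess[0] > 0 and guess[1] > 0:
        try:
            return _interior_fixed_point(params, guess, tol=1e-10)
        except SearchError:
            pass  # fall through to the generic solver

    z0 = np.log(np.maximum(guess, 1e-12))

    def residual(z):
        y = np.exp(np.clip(z, -700.0, 35.0))  # cap far beyond physical scales
        f = drift(y, params)
        scale = np.maximum(_turnover(y, params), 1e-30)
        return f / scale

    sol = optimize.root(residual, z0, method="hybr", options={"xtol": 1e-13})
    y = np.exp(np.clip(sol.x, -700.0, 35.0))
    if norm_residual(y) > tol:
        raise SearchError(
            f"fixed-point search did not converge (max relative residual "
            f"{norm_residual(y):.3g})"
        )
    return y


def jacobian(
    params: Parameters,
    point: np.ndarray,
    fd_scale: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Central finite-difference Jacobian of the drift and its eigenvalues.

    The step for component i is ``fd_scale * |y_i| + fd_scale**2`` so that
    species spanning many orders of magnitude are each perturbed relatively.
    Returns ``(J, eigenvalues)``.
    """
    y = np.asarray(point, dtype=np.float64)
    if np.any(y < 0):
        raise ValueError("point must be nonnegative")
    if fd_scale <= 0:
        raise ValueError("fd_scale must be positive")
    J = np.empty((N_SPECIES, N_SPECIES))
    for i in range(N_SPECIES):
        h = fd_scale * abs(y[i]) + fd_scale**2
        yp = y.copy()
        ym = y.copy()
        yp[i] += h
        ym[i] = max(ym[i] - h, 0.0)
        denom = yp[i] - ym[i]
        J[:, i] = (drift(yp, params) - drift(ym, params)) / denom
    if not np.all(np.isfinite(J)):
        raise FloatingPointError("non-finite entries in the Jacobian")
    return J, np.linalg.eigvals(J)


def _leading_eigenvalue(eigvals: np.ndarray) -> complex:
    return eigvals[int(np.argmax(eigvals.real))]


def oscillation_period(series: np.ndarray, dt: float,
                       floor_factor: float = 30.0) -> float:
    """Dominant oscillation period (h) of a uniformly sampled signal via FFT.

    The mean is removed and the period is 1/f* at the largest nonzero-
    frequency spectral peak.  Raises ``SearchError`` when no peak rises
    ``floor_factor`` times above the median spectral power (no oscillation).
    """
    x = np.asarray(series, dtype=np.float64)
    if x.ndim != 1 or len(x) < 8:
        raise ValueError("series must be 1-D with at least 8 samples")
    x = x - x.mean()
    power = np.abs(np.fft.rfft(x)) ** 2
    power[0] = 0.0
    freqs = np.fft.rfftfreq(len(x), d=dt)
    k = int(np.argmax(power))
    floor = np.median(power[1:])
    if k == 0 or power[k] <= floor_factor * max(floor, 1e-300):
        raise SearchError("no spectral peak above the noise floor")
    # quadratic interpolation of the log-power peak for sub-bin resolution
    f = freqs[k]
    if 1 <= k < len(power) - 1 and power[k - 1] > 0 and power[k + 1] > 0:
        lm, l0, lp = np.log(power[k - 1 : k + 2])
        denom = lm - 2 * l0 + lp
        if denom < 0:
            delta = 0.5 * (lm - lp) / denom
            f = freqs[k] + np.clip(delta, -0.5, 0.5) * (freqs[1] - freqs[0])
    return float(1.0 / f)


def autocorrelation_period(series: np.ndarray, dt: float) -> float:
    """Period from the first peak of the autocorrelation (independent check)."""
    x = np.asarray(series, dtype=np.float64)
    x = x - x.mean()
    n = len(x)
    acf = np.correlate(x, x, mode="full")[n - 1:]
    peaks, _ = signal.find_peaks(acf)
    if len(peaks) == 0:
        raise SearchError("autocorrelation has no secondary peak")
    return float(peaks[0] * dt)


@dataclass
class BifurcationResult:
    """Deterministic bifurcation scan along the E. coli degradation rate d."""

    d_grid: np.ndarray
    fixed_points: np.ndarray       # (n, 9); NaN rows where no interior point found
    leading_eigenvalues: np.ndarray  # (n,) complex
    regimes: list                  # per-d: "damped" | "sustained" | "extinct"
    hopf_d: Optional[float]        # first d with a positive-real complex pair
    extinction_d: Optional[float]  # first d with transient absorption to zero
    amplitudes: np.ndarray         # (n, 2, 2): (pop, [min, max]) post-transient
    periods: np.ndarray            # (n,), NaN where not oscillating
    flags: list                    # per-d disagreement notes ("" when clean)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "d": self.d_grid,
                "regime": self.regimes,
                "re_lambda": self.leading_eigenvalues.real,
                "im_lambda": self.leading_eigenvalues.imag,
                "c1_min": self.amplitudes[:, 0, 0],
                "c1_max": self.amplitudes[:, 0, 1],
                "c2_min": self.amplitudes[:, 1, 0],
                "c2_max": self.amplitudes[:, 1, 1],
                "period": self.periods,
                "flag": self.flags,
            }
        )


def _classify_transient(traj, tail_frac: float = 0.25,
                        amp_tol: float = 0.05) -> tuple[str, np.ndarray, float]:
    """Classify the post-transient behavior of a deterministic trajectory.

    Returns (regime, amplitudes (2,2), period).  "sustained" requires at
    least three cycles in the tail whose peak-to-trough amplitudes vary less
    than ``amp_tol`` between consecutive cycles and are non-negligible
    relative to the mean; a decaying envelope is "damped"; absorbed
    populations are "extinct".
    """
    if traj.extinct_at is not None:
        amps = np.zeros((2, 2))
        return "extinct", amps, np.nan
    n_tail = max(8, int(len(traj.times) * tail_frac))
    tail = traj.populations[-n_tail:]
    dt_rec = traj.times[1] - traj.times[0]
    amps = np.stack([
        [tail[:, 0].min(), tail[:, 0].max()],
        [tail[:, 1].min(), tail[:, 1].max()],
    ])
    x = tail[:, 0]
    mean = x.mean()
    rel_amp = (x.max() - x.min()) / max(mean, 1e-300)
    if rel_amp < 1e-3:
        return "damped", amps, np.nan
    peaks, _ = signal.find_peaks(x)
    troughs, _ = signal.find_peaks(-x)
    if len(peaks) < 3 or len(troughs) < 2:
        return "damped", amps, np.nan
    # peak-to-trough swing of consecutive cycles
    swings = []
    for k in range(min(len(peaks), len(troughs)) - 1):
        swings.append(x[peaks[k]] - x[troughs[k]])
    swings = np.array(swings[-6:])
    if np.any(swings <= 0):
        return "damped", amps, np.nan
    variation = np.max(np.abs(np.diff(swings))) / np.max(swings)
    if variation < amp_tol:
        try:
            period = oscillation_period(x, dt_rec)
        except SearchError:
            return "damped", amps, np.nan
        return "sustained", amps, period
    return "damped", amps, np.nan


def scan_bifurcation(
    params: Parameters,
    d_grid: Sequence[float],
    transient_horizon: float = 2000.0,
    inoculum: float = 5e4,
    dt: float = 0.005,
) -> BifurcationResult:
    """Scan the E. coli degradation rate d on the deterministic path.

    Per d: locate the interior coexistence fixed point (continued from the
    previous grid point), classify its stability from Jacobian eigenvalues,
    and cross-validate with a transient simulation from the standard
    inoculum.  Disagreements between the two routes are recorded in
    ``flags``, never silently dropped.
    """
    d_grid = np.asarray(sorted(d_grid), dtype=np.float64)
    n = len(d_grid)
    fps = np.full((n, N_SPECIES), np.nan)
    lead = np.full(n, np.nan, dtype=complex)
    regimes: list = []
    flags: list = []
    amplitudes = np.zeros((n, 2, 2))
    periods = np.full(n, np.nan)
    hopf_d: Optional[float] = None
    extinction_d: Optional[float] = None

    cfg = IntegratorConfig(t_end=transient_horizon, dt=dt, record_every=10)
    init = initial_state(c1=inoculum, c2=inoculum)
    guess = None
    for i, d in enumerate(d_grid):
        p = params.replace(d=d)
        traj = simulate(init, p, cfg, mode="deterministic")
        regime, amps, period = _classify_transient(traj)
        amplitudes[i] = amps
        periods[i] = period

        if guess is None:
            # first grid point: seed the continuation from the trajectory
            # midpoint average (close to the focus even when oscillating)
            tail = traj.states[len(traj.states) // 2:]
            guess = np.maximum(tail.mean(axis=0), 1e-12)
        eig_label = None
        try:
            fp = find_fixed_point(p, guess)
            interior = fp[0] > 1.0 and fp[1] > 1.0
            if interior:
                fps[i] = fp
                guess = fp
                _, eigvals = jacobian(p, fp)
                lam = _leading_eigenvalue(eigvals)
                lead[i] = lam
                if lam.real > 0 and abs(lam.imag) > 0:
                    eig_label = "oscillatory"
                    if hopf_d is None:
                        hopf_d = float(d)
                else:
                    eig_label = "stable"
        except SearchError:
            pass

        if regime == "extinct" and extinction_d is None:
            extinction_d = float(d)
        flag = ""
        if eig_label == "oscillatory" and regime == "damped":
            flag = "eigenvalues unstable but transient classified damped"
        elif eig_label == "stable" and regime == "sustained":
            flag = "eigenvalues stable but transient classified sustained"
        regimes.append(regime)
        flags.append(flag)

    return BifurcationResult(
        d_grid=d_grid, fixed_points=fps, leading_eigenvalues=lead,
        regimes=regimes, hopf_d=hopf_d, extinction_d=extinction_d,
        amplitudes=amplitudes, periods=periods, flags=flags,
    )


@dataclass
class NoiseScanResult:
    """Survival vs noise amplitude at fixed d, with the threshold epsilon."""

    epsilon_grid: np.ndarray
    survival_fractions: np.ndarray
    epsilon_star: Optional[float]   # largest eps: all survive AND period consistent
    epsilon_star_survival: Optional[float]  # largest eps with all surviving
    deterministic_period: Optional[float]
    stochastic_period: Optional[float]  # median over survivors at epsilon_star

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epsilon": self.epsilon_grid, "survival_fraction": self.survival_fractions}
        )


def noise_extinction_scan(
    params: Parameters,
    d: float,
    epsilon_grid: Sequence[float],
    n_replicates: int = 20,
    horizon: float = 1000.0,
    base_seed: int = 0,
    inoculum: float = 5e4,
    dt: float = 0.005,
    period_tol: float = 0.10,
) -> NoiseScanResult:
    """Fraction of replicates surviving per noise amplitude epsilon.

    Uses common random numbers across the epsilon grid.
    ``epsilon_star_survival`` is the largest grid value at which every
    replicate survives the horizon; ``epsilon_star`` additionally requires
    that the survivors keep oscillating at the deterministic period within
    ``period_tol``.  Single-trajectory spectral peaks are noisy, so the
    stochastic period is the median FFT period over all surviving replicates
    at a given amplitude.
    """
    eps_grid = np.asarray(sorted(epsilon_grid), dtype=np.float64)
    if np.any(eps_grid < 0) or np.any(eps_grid > 1):
        raise ValueError("epsilon values must lie in [0, 1]")
    p_d = params.replace(d=d)
    init = initial_state(c1=inoculum, c2=inoculum)

    def make_cfg(seed):
        return IntegratorConfig(t_end=horizon, dt=dt, record_every=10, seed=seed)

    fractions = np.empty(len(eps_grid))
    for k, eps in enumerate(eps_grid):
        p = p_d.replace(noise_scale=float(eps))
        summary = run_ensemble(init, p, make_cfg(base_seed), n_replicates)
        fractions[k] = survival_fraction(summary)

    full = np.where(fractions == 1.0)[0]
    eps_star_survival = float(eps_grid[full.max()]) if len(full) else None

    det_period = None
    try:
        det = simulate(init, p_d, make_cfg(base_seed), mode="deterministic")
        tail = det.populations[len(det.times) // 2:, 0]
        det_period = oscillation_period(tail, det.times[1] - det.times[0])
    except SearchError:
        pass

    def median_period(eps: float) -> Optional[float]:
        periods = []
        for i in range(n_replicates):
            p = p_d.replace(noise_scale=eps)
            sto = simulate(init, p, make_cfg(base_seed + i), mode="stochastic")
            if sto.extinct_at is not None:
                continue
            try:
                tail = sto.populations[len(sto.times) // 2:, 0]
                periods.append(
                    oscillation_period(tail, sto.times[1] - sto.times[0]))
            except SearchError:
                continue
        return float(np.median(periods)) if periods else None

    eps_star = None
    sto_period = None
    if det_period is not None:
        for k in full[::-1]:
            mp = median_period(float(eps_grid[k]))
            if mp is not None and abs(mp - det_period) <= period_tol * det_period:
                eps_star = float(eps_grid[k])
                sto_period = mp
                break
    return NoiseScanResult(
        epsilon_grid=eps_grid, survival_fractions=fractions,
        epsilon_star=eps_star, epsilon_star_survival=eps_star_survival,
        deterministic_period=det_period, stochastic_period=sto_period,
    )
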