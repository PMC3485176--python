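"""Time integration: Euler-Maruyama for the chemical Langevin equation.

The stochastic path draws one independent standard-normal increment per
reaction channel per step; the deterministic path is the same scheme with the
noise amplitude set to zero, i.e. explicit Euler on the drift.  Negative
excursions are clamped to zero and populations falling below an absorption
threshold (default one cell) are set to zero, from which they cannot recover.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .network import (
    N_SPECIES,
    SPECIES,
    Parameters,
    _validate_state,
    drift,
    noise_matrix,
)

__all__ = [
    "IntegratorConfig",
    "Trajectory",
    "IntegrationError",
    "step",
    "simulate",
    "time_to_steady_state",
]


class IntegrationError(RuntimeError):
    """A step produced a non-finite state; carries the offending time."""

    def __init__(self, time: float):
        super().__init__(f"integration produced a non-finite state at t = {time:g} h")
        self.time = time


@dataclass
class IntegratorConfig:
    """Step size, horizon and bookkeeping for one integration run.

    ``dt`` defaults to 0.005 h so the fastest first-order rates in the
    default parameter set (k8 = 5/h) satisfy k*dt <= 0.025; a convergence
    test guards the choice.  ``record_every`` thins the stored trajectory.
    """

    t_end: float = 50.0
    dt: float = 0.005
    record_every: int = 10
    extinction_threshold: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be positive")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if self.extinction_threshold < 0:
            raise ValueError("extinction_threshold must be >= 0")

    @property
    def n_steps(self) -> int:
        """Number of steps, rounded up to a whole number of record intervals."""
        n = int(np.ceil(round(self.t_end / self.dt, 9)))
        rem = n % self.record_every
        if rem:
            n += self.record_every - rem
        return n


@dataclass
class Trajectory:
    """One realization: a time grid and the aligned state history."""

    times: np.ndarray            # (T,), hours, starting at 0
    states: np.ndarray           # (T, 9) species counts
    seed: int
    mode: str                    # "stochastic" | "deterministic"
    extinct_at: Optional[float]  # time both populations absorbed, or None

    def species(self, name: str) -> np.ndarray:
        return self.states[:, SPECIES.index(name)]

    @property
    def populations(self) -> np.ndarray:
        """(T, 2) array of the two cell populations (c1, c2)."""
        return self.states[:, :2]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: columns time, species, value, seed, mode."""
        frames = []
        for i, name in enumerate(SPECIES):
            frames.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "species": name,
                        "value": self.states[:, i],
                        "seed": self.seed,
                        "mode": self.mode,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def step(
    state: np.ndarray,
    params: Parameters,
    dt: float,
    gaussian_draws: np.ndarray,
    extinction_threshold: float = 1.0,
) -> np.ndarray:
    """One Euler-Maruyama step (reference NumPy implementation).

    ``state + drift*dt + B @ (draws*sqrt(dt))`` followed by clamping at zero
    and population absorption.  With ``params.noise_scale == 0`` this is
    exactly the explicit-Euler ODE step regardless of the draws.
    """
    y = _validate_state(state)
    if dt <= 0:
        raise ValueError("dt must be positive")
    draws = np.asarray(gaussian_draws, dtype=np.float64)
    if draws.shape != (18,):
        raise ValueError("gaussian_draws must have shape (18,)")
    out = y + drift(y, params) * dt
    if params.noise_scale > 0:
        out = out + noise_matrix(y, params) @ (draws * np.sqrt(dt))
    out = np.clip(out, 0.0, None)
    for i in (0, 1):
        if out[i] < extinction_threshold:
            out[i] = 0.0
    if not np.all(np.isfinite(out)):
        raise IntegrationError(dt)
    return out


def simulate(
    initial: np.ndarray,
    params: Parameters,
    config: IntegratorConfig,
    mode: str = "stochastic",
) -> Trajectory:
    """Integrate one realization over [0, t_end].

    ``mode="deterministic"`` forces the noise amplitude to zero (drift-only
    explicit Euler); the random seed is then irrelevant but still recorded.
    Identical seed and config give a bitwise-identical trajectory.
    """
    if mode not in ("stochastic", "deterministic"):
        raise ValueError("mode must be 'stochastic' or 'deterministic'")
    y0 = _validate_state(initial)
    p = params.pack()
    if mode == "deterministic":
        p[26] = 0.0
    n_steps = config.n_steps
    n_rec = n_steps // config.record_every + 1
    record = np.empty((n_rec, N_SPECIES))
    status, bad_step, tz1, tz2 = _kernels.integrate(
        y0, p, config.dt, n_steps, config.record_every,
        config.extinction_threshold, config.seed, record,
    )
    if status != _kernels.OK:
        raise IntegrationError(bad_step * config.dt)
    times = np.arange(n_rec) * (config.dt * config.record_every)
    extinct_at = None
    if tz1 >= 0 and tz2 >= 0:
        extinct_at = max(tz1, tz2) * config.dt
    return Trajectory(times=times, states=record, seed=config.seed,
                      mode=mode, extinct_at=extinct_at)


def _population_series(obj) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(obj, Trajectory):
        return obj.times, obj.populations
    if hasattr(obj, "times") and hasattr(obj, "mean"):  # EnsembleSummary
        return np.asarray(obj.times), np.asarray(obj.mean)[:, :2]
    raise TypeError("expected a Trajectory or EnsembleSummary")


def time_to_steady_state(
    traj,
    rel_tol: float = 0.01,
    window: float = 5.0,
) -> Optional[float]:
    """Earliest time after which both populations stop changing.

    A trailing-window running mean m(t) (window shrinks near t = 0) is
    compared one window back; the steady-state time is the earliest t* >=
    window such that the relative change |m(t) - m(t - window)| / |m(t)|
    stays below ``rel_tol`` for every later time, for both populations.
    Returns None if the criterion is never met.
    """
    times, pops = _population_series(traj)
    if window <= 0 or rel_tol <= 0:
        raise ValueError("window and rel_tol must be positive")
    if window >= times[-1]:
        raise ValueError("window must be shorter than the trajectory")
    dt_rec = times[1] - times[0]
    w = max(1, int(round(window / dt_rec)))
    T = len(times)
    csum = np.vstack([np.zeros((1, 2)), np.cumsum(pops, axis=0)])
    idx = np.arange(T)
    lo = np.maximum(0, idx - w + 1)
    m = (csum[idx + 1] - csum[lo]) / (idx - lo + 1)[:, None]
    # relative change one window back, defined from the first full window
    viol = np.zeros(T, dtype=bool)
    for i in range(w, T):
        num = np.abs(m[i] - m[i - w])
        den = np.maximum(np.maximum(np.abs(m[i]), np.abs(m[i - w])), 1e-300)
        r = np.where((num == 0), 0.0, num / den)
        viol[i] = bool(np.any(r >= rel_tol))
    candidates = np.where(times >= window)[0]
    last_viol = np.max(np.where(viol)[0]) if viol.any() else -1
    for i in candidates:
        if i > last_viol:
            return float(times[i])
    return None
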