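"""Replicate colonies: ensemble statistics, survival and extinction counts.

Replicates are independent realizations differing only in their seed
(``base_seed + i``).  Means and standard deviations are taken over *all*
replicates, including extinct ones, so ensemble averages collapse when many
single trajectories reach zero; survivor-only statistics are available via a
flag.  The standard deviation is the sample (n-1) estimator, declared in the
output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .integrate import IntegrationError, IntegratorConfig
from .network import N_SPECIES, SPECIES, Parameters, _validate_state

__all__ = [
    "EnsembleSummary",
    "run_ensemble",
    "steady_state_stats",
    "survival_fraction",
]


@dataclass
class EnsembleSummary:
    """Per-time mean/SD over replicate trajectories plus terminal bookkeeping."""

    times: np.ndarray           # (T,)
    mean: np.ndarray            # (T, 9), over all replicates
    sd: np.ndarray              # (T, 9), sample SD (ddof=1; zero when n=1)
    n_replicates: int
    n_extinct: int              # replicates with both populations at zero at t_end
    terminal_states: np.ndarray  # (n, 9)
    first_zero_times: np.ndarray  # (n, 2), +inf where a population never absorbed
    base_seed: int
    mode: str
    sd_estimator: str = "sample (ddof=1)"

    def species_mean(self, name: str) -> np.ndarray:
        return self.mean[:, SPECIES.index(name)]

    def species_sd(self, name: str) -> np.ndarray:
        return self.sd[:, SPECIES.index(name)]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: time, species, mean, sd, n, n_extinct."""
        frames = []
        for i, name in enumerate(SPECIES):
            frames.append(
                pd.DataFrame(
                    {
                        "time": self.times,
                        "species": name,
                        "mean": self.mean[:, i],
                        "sd": self.sd[:, i],
                        "n": self.n_replicates,
                        "n_extinct": self.n_extinct,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def run_ensemble(
    initial: np.ndarray,
    params: Parameters,
    config: IntegratorConfig,
    n_replicates: int,
    mode: str = "stochastic",
) -> EnsembleSummary:
    """Simulate ``n_replicates`` independent colonies and summarize them.

    Replicate i uses seed ``config.seed + i``; the summary is reproducible
    given the base seed.  Any replicate whose integration fails raises — no
    silent exclusion.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if mode not in ("stochastic", "deterministic"):
        raise ValueError("mode must be 'stochastic' or 'deterministic'")
    y0 = _validate_state(initial)
    p = params.pack()
    if mode == "deterministic":
        p[26] = 0.0
    n_steps = config.n_steps
    re = config.record_every
    n_rec = n_steps // re + 1
    record = np.empty((n_rec, N_SPECIES))
    # Welford online moments: stable against the ~1e9-cell magnitudes
    mean = np.zeros((n_rec, N_SPECIES))
    m2 = np.zeros((n_rec, N_SPECIES))
    terminal = np.empty((n_replicates, N_SPECIES))
    first_zero = np.full((n_replicates, 2), np.inf)
    n_extinct = 0
    for i in range(n_replicates):
        seed = config.seed + i
        status, bad_step, tz1, tz2 = _kernels.integrate(
            y0, p, config.dt, n_steps, re,
            config.extinction_threshold, seed, record,
        )
        if status != _kernels.OK:
            raise IntegrationError(bad_step * config.dt)
        delta = record - mean
        mean += delta / (i + 1)
        m2 += delta * (record - mean)
        terminal[i] = record[-1]
        if tz1 >= 0:
            first_zero[i, 0] = tz1 * config.dt
        if tz2 >= 0:
            first_zero[i, 1] = tz2 * config.dt
        if tz1 >= 0 and tz2 >= 0:
            n_extinct += 1
    if n_replicates > 1:
        sd = np.sqrt(np.clip(m2 / (n_replicates - 1), 0.0, None))
    else:
        sd = np.zeros_like(mean)
    times = np.arange(n_rec) * (config.dt * re)
    return EnsembleSummary(
        times=times, mean=mean, sd=sd,
        n_replicates=n_replicates, n_extinct=n_extinct,
        terminal_states=terminal, first_zero_times=first_zero,
        base_seed=config.seed, mode=mode,
    )


def _nearest_index(times: np.ndarray, t_eval: float) -> int:
    if t_eval < times[0] or t_eval > times[-1]:
        raise ValueError(f"t_eval = {t_eval} outside recorded range "
                         f"[{times[0]}, {times[-1]}]")
    return int(np.argmin(np.abs(times - t_eval)))


def steady_state_stats(summary: EnsembleSummary, t_eval: float) -> pd.DataFrame:
    """Mean and SD of every species at the recorded time nearest ``t_eval``."""
    i = _nearest_index(summary.times, t_eval)
    return pd.DataFrame(
        {"mean": summary.mean[i], "sd": summary.sd[i]},
        index=pd.Index(SPECIES, name="species"),
    )


def survival_fraction(summary: EnsembleSummary, t_eval: Optional[float] = None) -> float:
    """Fraction of replicates with both populations above zero at ``t_eval``.

    Defaults to the end of the recorded window.  Populations cannot recover
    after absorbing to zero, so the first-zero times decide survival exactly.
    """
    if t_eval is None:
        t_eval = float(summary.times[-1])
    else:
        _nearest_index(summary.times, t_eval)  # range check
    alive = np.all(summary.first_zero_times > t_eval, axis=1)
    return float(np.mean(alive))
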