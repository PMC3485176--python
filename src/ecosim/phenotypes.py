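"""Ecological-regime classification and viability-threshold searches.

Maps antibiotic (Gc) levels to the ecological regime of the two-species
system — facultative mutualism, commensalism, obligatory mutualism or
extinction — and locates the viability boundaries: the monoculture Gc
limits, the lethal co-culture Gc, the minimum bioreactor carrying capacity
and the minimum inocula.

Survival is operationalized as a population sitting above the absorption
threshold (one cell) at a stated horizon.  Gc-threshold searches run on the
deterministic path (the boundaries are drift-dominated); inoculum and
carrying-capacity searches are ensemble statements and run stochastically
with common random numbers (shared seeds per candidate) so the monotone
bisection is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from . import _kernels
from .ensemble import EnsembleSummary, run_ensemble, survival_fraction
from .integrate import IntegrationError, IntegratorConfig, time_to_steady_state
from .network import Parameters, initial_state

__all__ = [
    "SearchError",
    "RegimeLabel",
    "classify_regime",
    "monoculture_gc_threshold",
    "coculture_lethal_gc",
    "min_carrying_capacity",
    "min_initial_population",
    "alpha_sweep",
    "AlphaSweepResult",
]

DEFAULT_INOCULUM = 5e4

_SPECIES_ALIASES = {
    "yeast": "yeast", "s_cerevisiae": "yeast", "c1": "yeast",
    "bacteria": "bacteria", "e_coli": "bacteria", "c2": "bacteria",
}


class SearchError(RuntimeError):
    """A threshold search failed (bracket does not straddle, grid exhausted)."""


@dataclass(frozen=True)
class RegimeLabel:
    """Ecological regime plus the three survival outcomes it derives from."""

    label: str
    yeast_alone: bool
    bacteria_alone: bool
    coculture: bool

    @staticmethod
    def from_survival(yeast_alone: bool, bacteria_alone: bool,
                      coculture: bool) -> "RegimeLabel":
        if not coculture:
            label = "extinction"
        elif yeast_alone and bacteria_alone:
            label = "facultative_mutualism"
        elif bacteria_alone:
            label = "commensalism_bacteria"
        elif yeast_alone:
            label = "commensalism_yeast"
        else:
            label = "obligatory_mutualism"
        return RegimeLabel(label, yeast_alone, bacteria_alone, coculture)


def _canonical_species(species: str) -> str:
    try:
        return _SPECIES_ALIASES[species.lower()]
    except KeyError:
        raise ValueError(f"unknown species {species!r}") from None


def _survives(initial, params, horizon, mode="deterministic", seed=0,
              dt=0.005, which="both", extinction_threshold=1.0) -> bool:
    """Survival query without trajectory recording (early exit on extinction)."""
    p = params.pack()
    if mode == "deterministic":
        p[26] = 0.0
    n_steps = int(np.ceil(round(horizon / dt, 9)))
    y_out = np.empty(9)
    status, bad_step, tz1, tz2 = _kernels.final_state(
        np.asarray(initial, dtype=np.float64), p, dt, n_steps,
        extinction_threshold, seed, y_out,
    )
    if status != _kernels.OK:
        raise IntegrationError(bad_step * dt)
    if which == "both":
        return tz1 < 0 and tz2 < 0
    return tz1 < 0 if which == "yeast" else tz2 < 0


def classify_regime(
    params: Parameters,
    Gc: float,
    mode: str = "deterministic",
    survival_horizon: float = 200.0,
    inoculum: float = DEFAULT_INOCULUM,
    seed: int = 0,
) -> RegimeLabel:
    """Classify the ecological regime at a given Gc concentration (M).

    Runs each monoculture and the co-culture at the stated inoculum and
    derives the regime label from which of them survive the horizon.
    """
    p = params.replace(Gc=Gc)
    yeast = _survives(initial_state(c1=inoculum), p, survival_horizon,
                      mode=mode, seed=seed, which="yeast")
    bact = _survives(initial_state(c2=inoculum), p, survival_horizon,
                     mode=mode, seed=seed, which="bacteria")
    co = _survives(initial_state(c1=inoculum, c2=inoculum), p,
                   survival_horizon, mode=mode, seed=seed, which="both")
    return RegimeLabel.from_survival(yeast, bact, co)


def _bisect_gc(predicate: Callable[[float], bool], lo: float, hi: float,
               tol: float) -> float:
    if not predicate(lo):
        raise SearchError(f"lower bracket Gc = {lo:g} M does not survive")
    if predicate(hi):
        raise SearchError(f"upper bracket Gc = {hi:g} M survives; "
                          "bracket does not straddle the boundary")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if predicate(mid):
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def monoculture_gc_threshold(
    params: Parameters,
    species: str,
    bracket: tuple[float, float],
    tol: float = 1e-9,
    survival_horizon: float = 2000.0,
    inoculum: float = DEFAULT_INOCULUM,
) -> float:
    """Survival/extinction Gc boundary (M) of one species grown alone.

    Deterministic bisection over Gc; with resistance absent this approaches
    the closed forms k1/k3 (yeast) and k2/k3 (bacteria) as the horizon grows
    (the finite horizon biases the boundary upward by ln(inoculum)/(k3*T)).
    """
    species = _canonical_species(species)
    init = (initial_state(c1=inoculum) if species == "yeast"
            else initial_state(c2=inoculum))

    def alive(gc: float) -> bool:
        return _survives(init, params.replace(Gc=gc), survival_horizon,
                         which=species)

    lo, hi = bracket
    return _bisect_gc(alive, lo, hi, tol)


def coculture_lethal_gc(
    params: Parameters,
    bracket: tuple[float, float],
    tol: float = 1e-7,
    survival_horizon: float = 200.0,
    inoculum: float = DEFAULT_INOCULUM,
    mode: str = "stochastic",
    n_replicates: int = 10,
    base_seed: int = 0,
) -> float:
    """Gc boundary (M) above which the two-species culture goes extinct.

    The boundary is an ensemble statement: whether the initial rescue race
    (resistance must build before the antibiotic clears the inoculum) is won
    depends on noise kicks in the induction cascade, and stochastic colonies
    survive well beyond the drift-only collapse point.  The default bisects
    on "at least one of ``n_replicates`` colonies survives the horizon"
    under common random numbers; ``mode="deterministic"`` bisects the
    drift-only system instead.
    """
    init = initial_state(c1=inoculum, c2=inoculum)

    if mode == "deterministic":
        def alive(gc: float) -> bool:
            return _survives(init, params.replace(Gc=gc), survival_horizon,
                             which="both")
    else:
        def alive(gc: float) -> bool:
            p = params.replace(Gc=gc)
            return any(
                _survives(init, p, survival_horizon, mode="stochastic",
                          seed=base_seed + i, which="both")
                for i in range(n_replicates)
            )

    lo, hi = bracket
    return _bisect_gc(alive, lo, hi, tol)


def _all_replicates_survive(initial, params, horizon, n_replicates,
                            base_seed, dt=0.005) -> bool:
    # common random numbers: replicate i always uses base_seed + i
    for i in range(n_replicates):
        if not _survives(initial, params, horizon, mode="stochastic",
                         seed=base_seed + i, dt=dt, which="both"):
            return False
    return True


def min_carrying_capacity(
    params: Parameters,
    n_replicates: int = 25,
    survival_horizon: float = 3000.0,
    base_seed: int = 0,
    inoculum: float = DEFAULT_INOCULUM,
    grid: Optional[Sequence[float]] = None,
    refine_rel: float = 0.1,
) -> float:
    """Smallest carrying capacity at which every replicate colony survives.

    Scans a log-spaced cmax grid for the first passing value, then bisects
    (in log space) between the last failing and first passing grid points to
    the stated relative resolution.  Stochastic: the result is tied to the
    seed set ``base_seed .. base_seed + n_replicates - 1``.
    """
    if grid is None:
        grid = [1e3 * 2**k for k in range(0, 12)]  # 1e3 .. 2.048e6
    grid = sorted(grid)
    init = initial_state(c1=inoculum, c2=inoculum)

    def ok(cmax: float) -> bool:
        return _all_replicates_survive(init, params.replace(cmax=cmax),
                                       survival_horizon, n_replicates,
                                       base_seed)

    lo = None
    hi = None
    for cmax in grid:
        if ok(cmax):
            hi = cmax
            break
        lo = cmax
    if hi is None:
        raise SearchError("no carrying capacity on the grid supports survival")
    if lo is None:
        return float(hi)
    while hi / lo > 1.0 + refine_rel:
        mid = float(np.sqrt(lo * hi))
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return float(hi)


def min_initial_population(
    params: Parameters,
    searched_species: str = "both",
    fixed_species: Optional[str] = None,
    fixed_count: Optional[float] = None,
    n_replicates: int = 25,
    survival_horizon: float = 1000.0,
    search_range: tuple[int, int] = (1, 1000),
    base_seed: int = 0,
) -> int:
    """Smallest integer inoculum for which all replicate colonies survive.

    ``searched_species="both"`` searches equal inocula of both species
    jointly; otherwise one species is searched while ``fixed_species`` starts
    at ``fixed_count`` cells.  Integer bisection under common random numbers.
    """
    lo, hi = search_range
    if lo < 0 or hi <= lo:
        raise ValueError("invalid search range")

    if searched_species == "both":
        if fixed_species is not None:
            raise ValueError("fixed_species must be None when searching both")

        def make_init(n: int):
            return initial_state(c1=n, c2=n)
    else:
        searched = _canonical_species(searched_species)
        fixed = _canonical_species(fixed_species or
                                   ("bacteria" if searched == "yeast" else "yeast"))
        if fixed == searched:
            raise ValueError("fixed and searched species must differ")
        if fixed_count is None or fixed_count < 0:
            raise ValueError("fixed_count must be >= 0")

        def make_init(n: int):
            c1 = n if searched == "yeast" else fixed_count
            c2 = n if searched == "bacteria" else fixed_count
            return initial_state(c1=c1, c2=c2)

    def ok(n: int) -> bool:
        return _all_replicates_survive(make_init(n), params, survival_horizon,
                                       n_replicates, base_seed)

    if not ok(hi):
        raise SearchError(f"no inoculum up to {hi} supports survival of all "
                          f"{n_replicates} replicates")
    if ok(lo):
        return lo
    # invariant: lo fails, hi passes
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return hi


@dataclass
class AlphaSweepResult:
    alpha: float
    unit: str
    summary: EnsembleSummary
    label: str  # "fast" | "slow" | "extinct"
    time_to_steady_state: Optional[float]


def alpha_sweep(
    params: Parameters,
    alpha_values: Sequence[float],
    unit: str,
    config: IntegratorConfig,
    n_replicates: int = 25,
    inoculum: float = DEFAULT_INOCULUM,
) -> list[AlphaSweepResult]:
    """Ensembles across resistance-attenuation values with a qualitative label.

    Labels: ``extinct`` when no replicate survives the horizon, ``fast`` when
    the ensemble means reach steady state within the horizon, otherwise
    ``slow`` (the strict slow/fast call uses a 10,000 h horizon via
    ``config.t_end``).  The unit tag is mandatory because the coefficient may
    be stated per molecule or per nM (converted per compartment volume).
    """
    results = []
    init = initial_state(c1=inoculum, c2=inoculum)
    for alpha in alpha_values:
        if alpha <= 0:
            raise ValueError("alpha values must be positive")
        p = params.with_alpha(alpha, unit=unit)
        summary = run_ensemble(init, p, config, n_replicates)
        if survival_fraction(summary) == 0.0:
            label, tss = "extinct", None
        else:
            tss = time_to_steady_state(summary)
            label = "fast" if tss is not None else "slow"
        results.append(AlphaSweepResult(alpha, unit, summary, label, tss))
    return results
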