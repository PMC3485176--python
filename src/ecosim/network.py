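"""Reaction network of the synthetic bacteria-yeast ecosystem.

The model couples two engineered populations growing in one well-mixed
bioreactor: *S. cerevisiae* (``c1``) and *E. coli* (``c2``).  Both are killed
by a growth-control antibiotic (Gc, e.g. kanamycin) unless protected by a
resistance protein (Res) whose expression each species induces in the *other*
via diffusible quorum-sensing signals (AHL1 produced by yeast, AHL2 by
bacteria).  The network has 17 core reactions plus an optional first-order
*E. coli* lysis channel (rate ``d``), acting on 9 dynamic species:

======  =========  =====================================================
index   name       meaning
======  =========  =====================================================
0       c1         S. cerevisiae population (cells)
1       c2         E. coli population (cells)
2       AHL1       yeast-produced signal (molecules)
3       AHL2       bacteria-produced signal (molecules)
4       C1         AHL1:AHLR1 complex in E. coli (molecules)
5       C2         AHL2:AHLR2 complex in yeast (molecules)
6       preRes1    yeast pre-resistance intermediate (molecules)
7       Res1       yeast resistance protein (molecules)
8       Res2       bacterial resistance protein (molecules)
======  =========  =====================================================

All species are stored as counts.  Rate laws written in concentration units
are converted with the compartment factors Omega1 = V1*Na (yeast-side
reactions 7 and 8) and Omega2 = V2*Na (E. coli-side reactions 10 and 11).
Receptor pools (AHLR1/AHLR2) and Gc are held at fixed concentrations and
folded into effective constants.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SPECIES",
    "N_SPECIES",
    "N_REACTIONS",
    "STOICHIOMETRY",
    "Parameters",
    "initial_state",
    "propensities",
    "drift",
    "noise_matrix",
]

SPECIES = ("c1", "c2", "AHL1", "AHL2", "C1", "C2", "preRes1", "Res1", "Res2")
N_SPECIES = 9
N_REACTIONS = 18

# Net stoichiometric change of each species (row) per reaction channel
# (column).  Reactions, 0-based:
#   0  logistic growth of yeast            c1 -> 2 c1
#   1  logistic growth of bacteria         c2 -> 2 c2
#   2  Gc killing of yeast                 c1 -> 0
#   3  Gc killing of bacteria              c2 -> 0
#   4  AHL1 synthesis by yeast             c1 -> c1 + AHL1
#   5  AHL2 synthesis by bacteria          c2 -> c2 + AHL2
#   6  AHL2 + receptor binding (yeast)     2 AHL2 -> C2
#   7  complex-induced preRes1 production  C2 -> C2 + preRes1   (catalytic)
#   8  preRes1 maturation                  preRes1 -> Res1
#   9  AHL1 + receptor binding (E. coli)   2 AHL1 -> C1
#   10 complex-induced Res2 production     C1 -> C1 + Res2      (catalytic)
#   11 AHL1 degradation
#   12 AHL2 degradation
#   13 C1 degradation
#   14 C2 degradation
#   15 Res1 degradation
#   16 Res2 degradation
#   17 E. coli lysis                       c2 -> 0   (rate d, off by default)
STOICHIOMETRY = np.zeros((N_SPECIES, N_REACTIONS), dtype=np.int64)
for _i, _j, _v in [
    (0, 0, +1),
    (1, 1, +1),
    (0, 2, -1),
    (1, 3, -1),
    (2, 4, +1),
    (3, 5, +1),
    (3, 6, -2), (5, 6, +1),
    (6, 7, +1),
    (6, 8, -1), (7, 8, +1),
    (2, 9, -2), (4, 9, +1),
    (8, 10, +1),
    (2, 11, -1),
    (3, 12, -1),
    (4, 13, -1),
    (5, 14, -1),
    (7, 15, -1),
    (8, 16, -1),
    (1, 17, -1),
]:
    STOICHIOMETRY[_i, _j] = _v
STOICHIOMETRY.setflags(write=False)


@dataclass(frozen=True)
class Parameters:
    """Kinetic constants, compartment volumes and fixed concentrations.

    Defaults are the published operating point of the ecosystem.  Units:
    first-order rates in h^-1, Gc and receptor pools in M, cmax in cells,
    volumes in L, ``alpha1``/``alpha2`` in molecules^-1, ``noise_scale``
    dimensionless in [0, 1].
    """

    k1: float = 0.234        # yeast max growth rate, 1/h
    k2: float = 0.936        # bacterial max growth rate, 1/h
    cmax: float = 1e9        # bioreactor carrying capacity, cells
    k3: float = 4e6          # Gc killing constant, 1/(M h)
    Gc: float = 3e-7         # growth-control (antibiotic) concentration, M
    alpha1: float = 5e4      # resistance attenuation, yeast side, 1/molecule
    alpha2: float = 5e4      # resistance attenuation, E. coli side, 1/molecule
    k4: float = 5e-6         # AHL1 production per yeast cell, 1/h
    k5: float = 5e-6         # AHL2 production per E. coli cell, 1/h
    k6: float = 3e19         # AHL2:receptor binding, 1/(M^3 h)
    k9: float = 3e19         # AHL1:receptor binding, 1/(M^3 h)
    AHLR1_conc: float = 5e-7  # fixed receptor pool in E. coli, M
    AHLR2_conc: float = 5e-7  # fixed receptor pool in yeast, M
    k7: float = 6e-5         # maximal preRes1 production, M/h
    k7b: float = 1e-8        # half-saturation of preRes1 induction, M
    n1: float = 1.0          # Hill coefficient, yeast side
    k10: float = 6e-5        # maximal Res2 production, M/h
    k10b: float = 1e-8       # half-saturation of Res2 induction, M
    n2: float = 1.0          # Hill coefficient, E. coli side
    k8: float = 5.0          # preRes1 -> Res1 maturation, 1/h
    k11: float = 1.19        # AHL1 degradation, 1/h
    k12: float = 1.19        # AHL2 degradation, 1/h
    k13: float = 1.386       # C1 degradation, 1/h
    k14: float = 1.386       # C2 degradation, 1/h
    k15: float = 4.0         # Res1 degradation, 1/h
    k16: float = 4.0         # Res2 degradation, 1/h
    V1: float = 3.7e-14      # yeast cell volume, L
    V2: float = 1e-15        # E. coli cell volume, L
    Na: float = 6.023e23     # Avogadro constant, 1/mol
    d: float = 0.0           # E. coli lysis/degradation rate, 1/h
    noise_scale: float = 1.0  # multiplier on all Langevin noise terms

    def __post_init__(self) -> None:
        for name in (
            "k1", "k2", "k3", "Gc", "alpha1", "alpha2", "k4", "k5", "k6",
            "k9", "AHLR1_conc", "AHLR2_conc", "k7", "k7b", "k10", "k10b",
            "k8", "k11", "k12", "k13", "k14", "k15", "k16", "d",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {name} must be finite and >= 0, got {v}")
        for name in ("cmax", "V1", "V2", "Na"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"parameter {name} must be finite and > 0, got {v}")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("Hill coefficients n1, n2 must be >= 1")
        if not 0.0 <= self.noise_scale <= 1.0:
            raise ValueError("noise_scale must lie in [0, 1]")

    # Effective constants are always recomputed from the primitives so they
    # can never go stale after a replace().
    @property
    def omega1(self) -> float:
        """Count-per-molar conversion of the yeast compartment, V1*Na."""
        return self.V1 * self.Na

    @property
    def omega2(self) -> float:
        """Count-per-molar conversion of the E. coli compartment, V2*Na."""
        return self.V2 * self.Na

    @property
    def k3_eff(self) -> float:
        """Killing rate at the fixed Gc concentration, k3*Gc (1/h)."""
        return self.k3 * self.Gc

    @property
    def k6_eff(self) -> float:
        """Binding constant with the receptor pool folded in, k6*AHLR2^2."""
        return self.k6 * self.AHLR2_conc**2

    @property
    def k9_eff(self) -> float:
        """Binding constant with the receptor pool folded in, k9*AHLR1^2."""
        return self.k9 * self.AHLR1_conc**2

    def replace(self, **changes) -> "Parameters":
        """Return a copy with the given fields replaced (re-validated)."""
        if "alpha" in changes:
            a = changes.pop("alpha")
            changes.setdefault("alpha1", a)
            changes.setdefault("alpha2", a)
        return dataclasses.replace(self, **changes)

    def with_alpha(self, value: float, unit: str = "molecules") -> "Parameters":
        """Set the resistance-attenuation coefficient in either unit scheme.

        ``unit="molecules"`` applies ``value`` (molecules^-1) to both species.
        ``unit="nM^-1"`` interprets ``value`` as a concentration-based
        coefficient and converts per compartment: alpha1 = value/(1e-9*Omega1),
        alpha2 = value/(1e-9*Omega2).
        """
        if unit in ("molecules", "molecules^-1", "per_molecule"):
            return self.replace(alpha1=value, alpha2=value)
        if unit in ("nM^-1", "nM-1", "per_nM"):
            return self.replace(
                alpha1=value / (1e-9 * self.omega1),
                alpha2=value / (1e-9 * self.omega2),
            )
        raise ValueError(f"unknown alpha unit {unit!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "Parameters":
        data = dict(data)
        if "alpha" in data:
            a = data.pop("alpha")
            data.setdefault("alpha1", a)
            data.setdefault("alpha2", a)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**data)

    def pack(self) -> np.ndarray:
        """Flatten to the float vector consumed by the integration kernels."""
        return np.array(
            [
                self.k1, self.k2, self.cmax, self.k3_eff,
                self.alpha1, self.alpha2, self.k4, self.k5,
                self.k6_eff, self.omega1, self.k7, self.k7b, self.n1,
                self.k8, self.k9_eff, self.omega2, self.k10, self.k10b,
                self.n2, self.k11, self.k12, self.k13, self.k14,
                self.k15, self.k16, self.d, self.noise_scale,
            ],
            dtype=np.float64,
        )


def initial_state(c1: float = 0.0, c2: float = 0.0, **molecules: float) -> np.ndarray:
    """Build a state vector from named species counts (others default to 0)."""
    y = np.zeros(N_SPECIES)
    y[0] = c1
    y[1] = c2
    for name, value in molecules.items():
        if name not in SPECIES:
            raise ValueError(f"unknown species {name!r}")
        y[SPECIES.index(name)] = value
    if np.any(y < 0):
        raise ValueError("species counts must be >= 0")
    return y


def _validate_state(state: np.ndarray) -> np.ndarray:
    state = np.asarray(state, dtype=np.float64)
    if state.shape != (N_SPECIES,):
        raise ValueError(f"state must have shape ({N_SPECIES},)")
    if np.any(state < 0) or not np.all(np.isfinite(state)):
        raise ValueError("state components must be finite and >= 0")
    return state


def propensities(state: np.ndarray, params: Parameters) -> np.ndarray:
    """Per-channel reaction rates (events/h) at the given state.

    Logistic growth propensities clamp to zero at or above carrying capacity;
    every entry is >= 0.
    """
    y = _validate_state(state)
    p = params
    a = np.zeros(N_REACTIONS)
    logistic = max(0.0, 1.0 - (y[0] + y[1]) / p.cmax)
    a[0] = p.k1 * y[0] * logistic
    a[1] = p.k2 * y[1] * logistic
    a[2] = p.k3_eff * y[0] / (1.0 + p.alpha1 * y[7])
    a[3] = p.k3_eff * y[1] / (1.0 + p.alpha2 * y[8])
    a[4] = p.k4 * y[0]
    a[5] = p.k5 * y[1]
    a[6] = p.k6_eff * y[3] ** 2 / p.omega1
    x = y[5] / p.omega1  # complex C2 as a yeast-compartment concentration
    a[7] = p.omega1 * p.k7 * x**p.n1 / (p.k7b**p.n1 + x**p.n1) if x > 0 else 0.0
    a[8] = p.k8 * y[6]
    a[9] = p.k9_eff * y[2] ** 2 / p.omega2
    z = y[4] / p.omega2
    a[10] = p.omega2 * p.k10 * z**p.n2 / (p.k10b**p.n2 + z**p.n2) if z > 0 else 0.0
    a[11] = p.k11 * y[2]
    a[12] = p.k12 * y[3]
    a[13] = p.k13 * y[4]
    a[14] = p.k14 * y[5]
    a[15] = p.k15 * y[7]
    a[16] = p.k16 * y[8]
    a[17] = p.d * y[1]
    return a


def drift(state: np.ndarray, params: Parameters) -> np.ndarray:
    """Deterministic time derivative of every species: S @ a (counts/h)."""
    return STOICHIOMETRY @ propensities(state, params)


def noise_matrix(state: np.ndarray, params: Parameters) -> np.ndarray:
    """Langevin diffusion coefficients, entry (i, j) = eps * nu_ij * sqrt(a_j)."""
    a = propensities(state, params)
    return params.noise_scale * STOICHIOMETRY * np.sqrt(np.clip(a, 0.0, None))
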