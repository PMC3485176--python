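"""YAML configuration: parameter files and experiment descriptors.

A config file is a flat mapping.  Keys matching :class:`ecosim.network.
Parameters` fields override the default kinetic constants (the bundled
``data/defaults.yaml`` reproduces them exactly); concentration-valued keys
accept unit-suffixed strings such as ``"250 nM"``.  Remaining keys describe
the experiment (name, sweep grid, replicate count, seed, output directory).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .network import Parameters

__all__ = ["ExperimentSpec", "parse_quantity", "load_config",
           "save_config", "default_parameters"]

EXPERIMENTS = (
    "baseline", "gc_sweep", "alpha_sweep", "cmax_sweep",
    "inoculum_search", "bifurcation", "noise_scan",
)

_PARAM_FIELDS = {f.name for f in dataclasses.fields(Parameters)} | {"alpha"}
_CONCENTRATION_KEYS = {"Gc", "AHLR1_conc", "AHLR2_conc", "k7b", "k10b"}

_UNIT_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6, "µM": 1e-6, "μM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


def parse_quantity(value) -> float:
    """Parse a number or a '<number> <unit>' concentration string to molar."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    parts = text.split()
    if len(parts) == 1:
        # possibly glued, e.g. "250nM"
        for unit, factor in _UNIT_FACTORS.items():
            if text.endswith(unit) and text[: -len(unit)].strip():
                try:
                    return float(text[: -len(unit)].strip()) * factor
                except ValueError:
                    continue
        return float(text)
    if len(parts) == 2 and parts[1] in _UNIT_FACTORS:
        return float(parts[0]) * _UNIT_FACTORS[parts[1]]
    raise ValueError(f"cannot parse quantity {value!r}")


@dataclass
class ExperimentSpec:
    """Descriptor for one reproducible experiment run."""

    name: str = "baseline"
    overrides: dict = field(default_factory=dict)
    grid: list = field(default_factory=list)
    grid_unit: Optional[str] = None   # mandatory for alpha sweeps
    n_replicates: int = 100
    base_seed: int = 0
    t_end: float = 50.0
    dt: float = 0.005
    record_every: int = 10
    initial_c1: float = 5e4
    initial_c2: float = 5e4
    output_dir: str = "ecosim-output"

    def __post_init__(self) -> None:
        if self.name not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment {self.name!r}; choose from {EXPERIMENTS}")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        unknown = set(self.overrides) - _PARAM_FIELDS
        if unknown:
            raise ValueError(f"unknown parameter override keys: {sorted(unknown)}")
        if self.name == "alpha_sweep" and self.grid and self.grid_unit is None:
            raise ValueError("alpha sweeps require an explicit grid_unit "
                             "('molecules' or 'nM^-1')")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_parameters() -> Parameters:
    """Parameters from the bundled defaults file (identical to Parameters())."""
    text = resources.files("ecosim").joinpath("data/defaults.yaml").read_text()
    data = yaml.safe_load(text)
    return _build_parameters(data)


def _build_parameters(mapping: dict) -> Parameters:
    clean = {}
    for key, value in mapping.items():
        if key in _CONCENTRATION_KEYS:
            clean[key] = parse_quantity(value)
        else:
            clean[key] = float(value)
    return Parameters.from_dict(clean)


def load_config(path) -> tuple[Parameters, ExperimentSpec]:
    """Read a flat YAML config into (Parameters, ExperimentSpec).

    Unrecognized keys are rejected before any simulation; an empty file
    yields the default parameter set and a baseline experiment.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key: value mapping")
    param_over = {k: v for k, v in data.items() if k in _PARAM_FIELDS}
    spec_fields = {f.name for f in dataclasses.fields(ExperimentSpec)}
    spec_kw = {k: v for k, v in data.items() if k in spec_fields}
    unknown = set(data) - _PARAM_FIELDS - spec_fields
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    params = _build_parameters(param_over) if param_over else Parameters()
    spec_kw.setdefault("overrides", {})
    spec = ExperimentSpec(**spec_kw)
    # keep the explicit parameter overrides on the spec for the sidecar
    spec.overrides = {**param_over, **spec.overrides}
    return params, spec


def save_config(params: Parameters, path) -> None:
    """Serialize a parameter set to a flat YAML file (lossless round trip)."""
    Path(path).write_text(
        yaml.safe_dump(params.to_dict(), sort_keys=True, default_flow_style=False)
    )
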