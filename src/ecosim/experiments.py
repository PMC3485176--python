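"""One-command experiment runner: dispatch, CSV outputs, JSON sidecar."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentSpec, parse_quantity
from .ensemble import run_ensemble, steady_state_stats, survival_fraction
from .integrate import IntegratorConfig, time_to_steady_state
from .network import Parameters, initial_state
from .oscillation import noise_extinction_scan, scan_bifurcation
from .phenotypes import alpha_sweep, min_initial_population

__all__ = ["run_experiment"]

log = logging.getLogger("ecosim")


def _config(spec: ExperimentSpec) -> IntegratorConfig:
    return IntegratorConfig(t_end=spec.t_end, dt=spec.dt,
                            record_every=spec.record_every, seed=spec.base_seed)


def _apply_overrides(params: Parameters, spec: ExperimentSpec) -> Parameters:
    over = {}
    for key, value in spec.overrides.items():
        over[key] = parse_quantity(value) if isinstance(value, str) else value
    return params.replace(**over) if over else params


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)
    log.info("wrote %s (%d rows)", path, len(df))


def run_experiment(spec: ExperimentSpec, params: Parameters | None = None,
                   output_dir=None) -> dict:
    """Run one named experiment and write its tables plus a JSON sidecar.

    Returns a dict mapping output names to file paths.  Identical specs
    produce identical outputs (all randomness flows from ``base_seed``).
    """
    params = _apply_overrides(params or Parameters(), spec)
    out = Path(output_dir or spec.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = _config(spec)
    init = initial_state(c1=spec.initial_c1, c2=spec.initial_c2)
    written: dict[str, Path] = {}

    def ensemble_rows(summary, label_name, label_value):
        stats = steady_state_stats(summary, float(summary.times[-1]))
        return {
            label_name: label_value,
            "survival_fraction": survival_fraction(summary),
            "n_extinct": summary.n_extinct,
            "c1_mean": stats.loc["c1", "mean"],
            "c1_sd": stats.loc["c1", "sd"],
            "c2_mean": stats.loc["c2", "mean"],
            "c2_sd": stats.loc["c2", "sd"],
        }

    if spec.name == "baseline":
        summary = run_ensemble(init, params, cfg, spec.n_replicates)
        _write(summary.to_frame(), out / "baseline_summary.csv")
        written["summary"] = out / "baseline_summary.csv"
        tss = time_to_steady_state(summary, window=min(5.0, spec.t_end / 2))
        pd.DataFrame([{**ensemble_rows(summary, "experiment", "baseline"),
                       "time_to_steady_state": tss}]).to_csv(
            out / "baseline_stats.csv", index=False)
        written["stats"] = out / "baseline_stats.csv"
    elif spec.name == "gc_sweep":
        rows = []
        for gc in spec.grid:
            p = params.replace(Gc=parse_quantity(gc))
            summary = run_ensemble(init, p, cfg, spec.n_replicates)
            rows.append(ensemble_rows(summary, "Gc", p.Gc))
        _write(pd.DataFrame(rows), out / "gc_sweep.csv")
        written["sweep"] = out / "gc_sweep.csv"
    elif spec.name == "cmax_sweep":
        rows = []
        for cmax in spec.grid:
            p = params.replace(cmax=float(cmax))
            summary = run_ensemble(init, p, cfg, spec.n_replicates)
            rows.append(ensemble_rows(summary, "cmax", p.cmax))
        _write(pd.DataFrame(rows), out / "cmax_sweep.csv")
        written["sweep"] = out / "cmax_sweep.csv"
    elif spec.name == "alpha_sweep":
        alphas = [float(parse_quantity(g)) for g in spec.grid]
        results = alpha_sweep(params, alphas, spec.grid_unit, cfg,
                              n_replicates=spec.n_replicates,
                              inoculum=spec.initial_c1)
        rows = []
        for r in results:
            rows.append({**ensemble_rows(r.summary, "alpha", r.alpha),
                         "unit": r.unit, "label": r.label,
                         "time_to_steady_state": r.time_to_steady_state})
        _write(pd.DataFrame(rows), out / "alpha_sweep.csv")
        written["sweep"] = out / "alpha_sweep.csv"
    elif spec.name == "inoculum_search":
        n_min = min_initial_population(
            params, searched_species="both",
            n_replicates=spec.n_replicates,
            survival_horizon=spec.t_end, base_seed=spec.base_seed)
        _write(pd.DataFrame([{"min_equal_inoculum": n_min}]),
               out / "inoculum_search.csv")
        written["search"] = out / "inoculum_search.csv"
    elif spec.name == "bifurcation":
        grid = spec.grid or np.arange(0.10, 1.0 + 1e-9, 0.01)
        result = scan_bifurcation(params, grid, inoculum=spec.initial_c1,
                                  dt=spec.dt)
        _write(result.to_frame(), out / "bifurcation.csv")
        written["scan"] = out / "bifurcation.csv"
        for flag_d, flag in zip(result.d_grid, result.flags):
            if flag:
                log.info("d = %.3f: %s", flag_d, flag)
    elif spec.name == "noise_scan":
        grid = spec.grid or np.arange(0.0025, 0.0301, 0.0025)
        result = noise_extinction_scan(
            params, d=params.d, epsilon_grid=grid,
            n_replicates=spec.n_replicates, horizon=spec.t_end,
            base_seed=spec.base_seed, inoculum=spec.initial_c1, dt=spec.dt)
        _write(result.to_frame(), out / "noise_scan.csv")
        written["scan"] = out / "noise_scan.csv"
    else:  # pragma: no cover - ExperimentSpec already validates
        raise ValueError(f"unknown experiment {spec.name!r}")

    sidecar = {
        "version": __version__,
        "experiment": {**spec.to_dict(),
                       "grid": [float(parse_quantity(g)) if isinstance(g, str)
                                else float(g) for g in spec.grid]},
        "parameters": params.to_dict(),
        "dt": spec.dt,
        "base_seed": spec.base_seed,
        "sd_estimator": "sample (ddof=1)",
    }
    sidecar_path = out / f"{spec.name}_metadata.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    written["metadata"] = sidecar_path
    return written
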