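"""Named sensitivity scenarios and the dilution-rate study.

A scenario is a set of configuration overrides applied to a copy of the
baseline configuration; baseline and scenario are solved over the same
velocity grid and compared point by point.  Built-ins cover the studied
perturbations: a 10% higher maximum yield, a tenfold lower substrate
affinity constant, operation at 45 C with unchanged microbial parameters,
a threefold kLa gain from coalescence inhibition, and air instead of pure
O2.  All runs are deterministic: identical configurations give
bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .api import configured_stoichiometry, solve_config, sweep_config
from .config import ModelConfig, validate_config
from .errors import WashoutError
from .heat_cooling import heat_balance

DEFAULT_GRID = (0.04, 0.10, 0.15, 0.20, 0.25, 0.30)


@dataclass(frozen=True)
class Scenario:
    """Configuration overrides relative to a baseline (never mutated)."""

    name: str
    overrides: Mapping
    description: str = ""
    vsg_grid: tuple[float, ...] | None = None


def builtin_scenarios() -> dict[str, Scenario]:
    return {s.name: s for s in (
        Scenario("yield10",
                 {"kinetics": {"Y_xs_max_g_per_g": 0.63 * 1.1}},
                 "maximum biomass yield raised 10% (0.63 -> 0.693 g/g)"),
        Scenario("ks10",
                 {"kinetics": {"K_S_mol_per_kg": 5.0e-5}},
                 "substrate affinity constant lowered tenfold"),
        Scenario("hot45",
                 {"operation": {"temperature_C": 45.0}},
                 "fermentation at 45 C, microbial parameters unchanged"),
        Scenario("coalescence3",
                 {"correlations": {"coalescence_factor": 3.0}},
                 "coalescence inhibition raising kLa threefold"),
        Scenario("air",
                 {"operation": {"y_O2_in": 0.21}},
                 "air sparging instead of pure O2"),
    )}


def _merge(base: dict, overrides: Mapping) -> dict:
    out = dict(base)
    for key, val in overrides.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def apply_overrides(config: ModelConfig, overrides: Mapping) -> ModelConfig:
    """Validated copy of ``config`` with nested overrides applied."""
    return validate_config(_merge(config.model_dump(), overrides))


_METRICS = ("N_O2", "C_x", "R_x_kg_h", "O2_utilization", "Q_cool")


def run_scenario(scenario: Scenario, config: ModelConfig,
                 vsg_grid: Sequence[float] | None = None) -> pd.DataFrame:
    """Solve baseline and scenario on a common grid and tabulate deltas.

    One row per converged velocity; for each compared metric the table holds
    the baseline value, the scenario value and the percent change.
    """
    grid = tuple(vsg_grid if vsg_grid is not None
                 else scenario.vsg_grid or DEFAULT_GRID)
    varied = apply_overrides(config, scenario.overrides)
    base_props, var_props = config.physical_properties(), varied.physical_properties()

    rows = []
    for v in grid:
        row: dict = {"vsG_mean": v}
        for tag, cfg, props in (("baseline", config, base_props),
                                ("scenario", varied, var_props)):
            point_cfg = apply_overrides(
                cfg, {"operation": {"vsG_mean_m_per_s": float(v)}})
            try:
                sol = solve_config(point_cfg)
            except Exception as exc:  # noqa: BLE001 - reported per point
                row[f"{tag}_error"] = str(exc)
                continue
            heat = heat_balance(sol, props)
            values = {"N_O2": sol.N_O2, "C_x": sol.C_x,
                      "R_x_kg_h": sol.R_x_kg_h,
                      "O2_utilization": sol.O2_utilization,
                      "Q_cool": heat.Q_cool}
            for metric, val in values.items():
                row[f"{tag}_{metric}"] = val
        for metric in _METRICS:
            b, s = row.get(f"baseline_{metric}"), row.get(f"scenario_{metric}")
            if b is not None and s is not None:
                row[f"delta_pct_{metric}"] = (s / b - 1.0) * 100.0
        rows.append(row)
    return pd.DataFrame(rows)


def dilution_rate_study(D_grid: Sequence[float],
                        config: ModelConfig) -> pd.DataFrame:
    """Yield and residual substrate vs dilution rate (stoichiometry only).

    Washout points are flagged in the ``washout`` column, not fatal.
    """
    rows = []
    for D in np.asarray(D_grid, dtype=float):
        try:
            st = configured_stoichiometry(config, mu=float(D))
        except WashoutError as exc:
            rows.append({"D": D, "Y_xs": np.nan, "C_S": np.nan,
                         "washout": True, "note": str(exc)})
            continue
        rows.append({"D": D, "Y_xs": st.Y_xs, "C_S": st.residual_CS,
                     "washout": False, "note": ""})
    return pd.DataFrame(rows)
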