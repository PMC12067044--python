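"""Serialization of solutions: unit-annotated CSV, nested JSON, manifests."""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable

import pandas as pd

from . import __version__
from .config import ModelConfig, config_hash
from .hydrodynamics import GasColumnState
from .steady_state import OperatingPoint, SteadyStateSolution
from .stoichiometry import MolecularFormula, ProcessStoichiometry

#: units of the flat (CSV) columns
UNITS = {
    "vsG_mean": "m/s", "vsG_top": "m/s", "vsG_bot": "m/s",
    "FG_N_in": "mol/h", "FG_N_out": "mol/h", "M_L": "kg",
    "N_O2": "mol/(kg_L h)", "N_CO2": "mol/(kg_L h)", "N_W": "mol/(kg_L h)",
    "y_O2_out": "-", "y_CO2_out": "-", "y_N2_out": "-", "y_W_out": "-",
    "p_top": "bar", "p_bot": "bar", "eps_G": "-",
    "kla_O2": "1/h", "kla_CO2": "1/h",
    "C_x": "g/kg_L", "C_S": "mol/kg_L", "C_CO2": "mol/kg_L",
    "C_S_in": "g/kg", "R_x_kg_h": "kg/h",
    "F_L_out": "kg/h", "F_S_feed": "kg/h", "F_N_feed": "kg/h",
    "O2_utilization": "%", "ethanol_utilization": "%",
    "carbon_balance_error": "%", "D": "1/h", "T_C": "C",
}


def solution_to_dict(sol: SteadyStateSolution) -> dict:
    """Nested, JSON-serializable form of a solution (round-trips)."""
    d = dataclasses.asdict(sol)
    d["stoich"]["nu"] = dict(d["stoich"]["nu"])
    return d


def solution_from_dict(data: dict) -> SteadyStateSolution:
    data = json.loads(json.dumps(data))  # deep copy
    data["op"] = OperatingPoint(**data["op"])
    st = data["stoich"]
    st["biomass"] = MolecularFormula(**st["biomass"])
    st["substrate"] = MolecularFormula(**st["substrate"])
    data["stoich"] = ProcessStoichiometry(**st)
    data["gas"] = GasColumnState(**data["gas"])
    return SteadyStateSolution(**data)


def _flat_row(sol: SteadyStateSolution) -> dict:
    g = sol.gas
    return {
        "D": sol.op.D, "T_C": sol.op.T_C, "vsG_mean": g.vsG_mean,
        "vsG_top": g.vsG_top, "vsG_bot": g.vsG_bot,
        "FG_N_in": g.FG_N_in, "FG_N_out": g.FG_N_out, "M_L": sol.M_L,
        "N_O2": sol.N_O2, "N_CO2": sol.N_CO2, "N_W": sol.N_W,
        "y_O2_out": g.y_O2, "y_CO2_out": g.y_CO2, "y_N2_out": g.y_N2,
        "y_W_out": g.y_W, "p_top": g.p_top, "p_bot": g.p_bot,
        "eps_G": g.eps_G, "kla_O2": sol.kla_O2, "kla_CO2": sol.kla_CO2,
        "C_x": sol.C_x, "C_S": sol.C_S, "C_CO2": sol.C_CO2,
        "C_S_in": sol.C_S_in, "R_x_kg_h": sol.R_x_kg_h,
        "F_L_out": sol.F_L_out, "F_S_feed": sol.F_S_feed,
        "F_N_feed": sol.F_N_feed, "O2_utilization": sol.O2_utilization,
        "ethanol_utilization": sol.ethanol_utilization,
        "carbon_balance_error": sol.carbon_balance_error,
    }


def solutions_frame(solutions: Iterable[SteadyStateSolution],
                    annotate_units: bool = True) -> pd.DataFrame:
    df = pd.DataFrame([_flat_row(s) for s in solutions])
    if annotate_units:
        df.columns = [f"{c} [{UNITS[c]}]" if c in UNITS else c
                      for c in df.columns]
    return df


def write_report(solutions: Iterable[SteadyStateSolution] | SteadyStateSolution,
                 out_path: str | Path, fmt: str = "csv",
                 config: ModelConfig | None = None) -> Path:
    """Write solutions to ``out_path`` as CSV or JSON, plus a run manifest."""
    if isinstance(solutions, SteadyStateSolution):
        solutions = [solutions]
    solutions = list(solutions)
    if not solutions:
        raise ValueError("write_report requires at least one solution")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "csv":
        solutions_frame(solutions).to_csv(out_path, index=False)
    elif fmt == "json":
        payload = [solution_to_dict(s) for s in solutions]
        out_path.write_text(json.dumps(payload, indent=2))
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    manifest = {
        "tool": "scpreactor",
        "version": __version__,
        "generated_utc": datetime.now(timezone.utc).isoformat(),
        "n_points": len(solutions),
        "format": fmt,
        "config_sha256": config_hash(config) if config is not None else None,
    }
    manifest_path = out_path.with_suffix(out_path.suffix + ".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return out_path
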