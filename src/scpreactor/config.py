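"""Structured configuration: validated TOML in, domain objects out.

Every physical constant, correlation coefficient and operational choice of
the model lives here rather than inline in the computation modules, so the
full parameterisation of a run is a single overridable document.  The
defaults reproduce the base case: a 600 m^3 column (H/D = 6, 95% filled),
pure O2 at 1.2 bar overhead, 30 C, dilution rate 0.15 1/h.

An empty file (or ``load_config(None)``) yields the full default
configuration; unknown keys and out-of-range values are rejected with the
offending key named.
"""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path
from typing import Literal, Mapping

from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError
from .heat_cooling import CoolingParameters
from .hydrodynamics import CorrelationSet, ReactorGeometry
from .properties import (DIFFUSIVITY_DEFAULT, HENRY_REF_DEFAULT,
                         HENRY_VANT_HOFF_DEFAULT, PhysicalProperties)
from .regimes import TimeStrategies
from .steady_state import OperatingPoint
from .stoichiometry import KineticParameters, MolecularFormula


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class GeometryConfig(_Block):
    vessel_volume_m3: float = Field(600.0, gt=0)
    aspect_ratio: float = Field(6.0, gt=0, description="H_R/D_R")
    fill_fraction: float = Field(0.95, gt=0, le=1,
                                 description="aerated broth fraction of V_R")


class OperationConfig(_Block):
    dilution_rate_per_h: float = Field(0.15, gt=0)
    temperature_C: float = Field(30.0, gt=0, lt=100)
    p_top_bar: float = Field(1.2, gt=0)
    y_O2_in: float = Field(1.0, gt=0, le=1,
                           description="1.0 pure O2, 0.21 air")
    C_O2_set_mol_per_kg: float = Field(6.9e-5, gt=0)
    C_NH3_residual_g_per_kg: float = Field(1.0, ge=0)
    N_feed_concentration_g_per_kg: float = Field(200.0, gt=0)
    vsG_mean_m_per_s: float | None = Field(0.30, gt=0)
    vsG_top_m_per_s: float | None = Field(None, gt=0)


class KineticsConfig(_Block):
    mu_max_per_h: float = Field(0.22, gt=0)
    K_S_mol_per_kg: float = Field(5.0e-4, gt=0)
    Y_xs_max_g_per_g: float = Field(0.63, gt=0)
    m_S_mol_per_molx_h: float = Field(0.005, gt=0)
    qS_max_mol_per_molx_h: float | None = Field(
        None, gt=0, description="None: Herbert-Pirt value at mu_max")


class CompositionConfig(_Block):
    biomass_formula: str = "CH1.8O0.5N0.2"
    biomass_molar_mass_g_per_mol: float | None = Field(
        24.6, gt=0, description="conventional rounded value; None: computed")
    substrate_formula: str = "C2H6O"


class PropertiesConfig(_Block):
    henry_ref_mol_per_kg_bar: Mapping[str, float] = Field(
        default_factory=lambda: dict(HENRY_REF_DEFAULT),
        description="solubility in pure water at henry_T_ref_K")
    henry_vant_hoff_K: Mapping[str, float] = Field(
        default_factory=lambda: dict(HENRY_VANT_HOFF_DEFAULT))
    henry_T_ref_K: float = 298.15
    diffusivity_m2_per_s: Mapping[str, float] = Field(
        default_factory=lambda: dict(DIFFUSIVITY_DEFAULT))
    diffusivity_ratio_CO2_O2: float | None = Field(
        None, gt=0, description="direct override of D_CO2/D_O2")
    rho_L_kg_per_m3: float = Field(1000.0, gt=0)
    cp_kJ_per_kg_K: float = Field(4.18, gt=0)
    dH_evap_kJ_per_mol: float = Field(43.5, gt=0)
    heat_per_O2_kJ_per_mol: float = Field(460.0, gt=0)
    U_kW_per_m2_K: float = Field(1.4, gt=0)
    antoine_A: float = 5.11564
    antoine_B: float = 1687.537
    antoine_C: float = 42.98


class CorrelationsConfig(_Block):
    kla_coefficient: float = Field(0.32, gt=0)
    kla_exponent: float = Field(0.7, gt=0)
    kla_temperature_base: float = Field(1.022, gt=0)
    kla_reference_T_C: float = 20.0
    holdup_coefficient: float = Field(0.6, gt=0)
    holdup_exponent: float = Field(0.7, gt=0)
    coalescence_factor: float = Field(1.0, gt=0)
    pressure_average: Literal["log_mean", "arith_mean", "top"] = "log_mean"
    velocity_window_m_per_s: tuple[float, float] = (0.04, 0.30)


class CoolingConfig(_Block):
    dT_lm_K: float = Field(15.0, gt=0)
    dT_loop_K: float = Field(15.0, gt=0)
    unit_area_max_m2: float = Field(430.0, gt=0)
    unit_area_design_m2: float = Field(400.0, gt=0)
    tubes_per_unit: int = Field(1269, gt=0)
    tube_id_m: float = Field(0.019, gt=0)
    tube_length_m: float = Field(6.1, gt=0)
    scale_tubes_to_design_area: bool = True
    viscosity_Pa_s: float = Field(0.010, gt=0)
    wall_shear_model: Literal["simple", "laminar"] = "simple"
    extra_piping_m: float = Field(10.0, ge=0)
    pump_rpm_min: float = Field(60.0, gt=0)
    pump_rpm_max: float = Field(600.0, gt=0)
    impeller_diameter_m: float = Field(0.6, gt=0)
    clearance_m: float = Field(3.0e-4, gt=0)


class RegimesConfig(_Block):
    mix_circulations: float = Field(4.0, gt=0)
    gas_mixing_speedup: float = Field(3.0, gt=0)
    dT_allowed_K: float = Field(1.0, gt=0)
    gradient_threshold: float = Field(10.0, gt=0)


class ModelConfig(_Block):
    geometry: GeometryConfig = GeometryConfig()
    operation: OperationConfig = OperationConfig()
    kinetics: KineticsConfig = KineticsConfig()
    composition: CompositionConfig = CompositionConfig()
    properties: PropertiesConfig = PropertiesConfig()
    correlations: CorrelationsConfig = CorrelationsConfig()
    cooling: CoolingConfig = CoolingConfig()
    regimes: RegimesConfig = RegimesConfig()

    # ---- builders -------------------------------------------------------
    def reactor_geometry(self) -> ReactorGeometry:
        g = self.geometry
        return ReactorGeometry(V_R=g.vessel_volume_m3,
                               aspect_ratio=g.aspect_ratio,
                               fill_fraction=g.fill_fraction)

    def physical_properties(self) -> PhysicalProperties:
        p = self.properties
        return PhysicalProperties(
            henry_ref=dict(p.henry_ref_mol_per_kg_bar),
            henry_vant_hoff=dict(p.henry_vant_hoff_K),
            diffusivity=dict(p.diffusivity_m2_per_s),
            diffusivity_ratio_CO2_O2=p.diffusivity_ratio_CO2_O2,
            rho_L=p.rho_L_kg_per_m3, cp=p.cp_kJ_per_kg_K,
            dH_evap=p.dH_evap_kJ_per_mol,
            heat_per_O2=p.heat_per_O2_kJ_per_mol, U=p.U_kW_per_m2_K,
            antoine=(p.antoine_A, p.antoine_B, p.antoine_C),
            T_ref=p.henry_T_ref_K)

    def kinetic_parameters(self) -> KineticParameters:
        k = self.kinetics
        return KineticParameters(mu_max=k.mu_max_per_h, K_S=k.K_S_mol_per_kg,
                                 Y_xs_max=k.Y_xs_max_g_per_g,
                                 m_S=k.m_S_mol_per_molx_h,
                                 qS_max=k.qS_max_mol_per_molx_h)

    def biomass_formula(self) -> MolecularFormula:
        f = MolecularFormula.from_string(self.composition.biomass_formula)
        override = self.composition.biomass_molar_mass_g_per_mol
        if override is not None:
            f = MolecularFormula(C=f.C, H=f.H, O=f.O, N=f.N,
                                 molar_mass_override=override)
        return f

    def substrate_formula(self) -> MolecularFormula:
        return MolecularFormula.from_string(self.composition.substrate_formula)

    def operating_point(self) -> OperatingPoint:
        o = self.operation
        return OperatingPoint(
            D=o.dilution_rate_per_h, T_C=o.temperature_C, p_top=o.p_top_bar,
            y_O2_in=o.y_O2_in, C_O2_set=o.C_O2_set_mol_per_kg,
            C_NH3_residual=o.C_NH3_residual_g_per_kg,
            N_feed_concentration=o.N_feed_concentration_g_per_kg,
            vsG_mean=o.vsG_mean_m_per_s, vsG_top=o.vsG_top_m_per_s)

    def correlation_set(self) -> CorrelationSet:
        c = self.correlations
        return CorrelationSet(
            kla_coefficient=c.kla_coefficient, kla_exponent=c.kla_exponent,
            kla_temperature_base=c.kla_temperature_base,
            kla_reference_T_C=c.kla_reference_T_C,
            holdup_coefficient=c.holdup_coefficient,
            holdup_exponent=c.holdup_exponent,
            coalescence_factor=c.coalescence_factor,
            pressure_average=c.pressure_average,
            velocity_window=tuple(c.velocity_window_m_per_s))

    def cooling_parameters(self) -> CoolingParameters:
        c = self.cooling
        return CoolingParameters(
            dT_lm=c.dT_lm_K, dT_loop=c.dT_loop_K,
            unit_area_max=c.unit_area_max_m2,
            unit_area_design=c.unit_area_design_m2,
            tubes_per_unit=c.tubes_per_unit, tube_id=c.tube_id_m,
            tube_length=c.tube_length_m,
            scale_tubes_to_design_area=c.scale_tubes_to_design_area,
            viscosity=c.viscosity_Pa_s, wall_shear_model=c.wall_shear_model,
            extra_piping=c.extra_piping_m,
            pump_rpm=(c.pump_rpm_min, c.pump_rpm_max),
            impeller_diameter=c.impeller_diameter_m, clearance=c.clearance_m)

    def time_strategies(self) -> TimeStrategies:
        r = self.regimes
        return TimeStrategies(mix_circulations=r.mix_circulations,
                              gas_mixing_speedup=r.gas_mixing_speedup,
                              dT_allowed=r.dT_allowed_K)


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load and validate a TOML configuration; ``None`` gives the defaults."""
    if path is None:
        return ModelConfig()
    try:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    except FileNotFoundError as exc:
        raise ConfigError(f"configuration file not found: {path}") from exc
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return validate_config(data)


def validate_config(data: Mapping) -> ModelConfig:
    try:
        return ModelConfig.model_validate(data)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            key = ".".join(str(p) for p in err["loc"])
            lines.append(f"{key}: {err['msg']}")
        raise ConfigError("invalid configuration: " + "; ".join(lines)) from exc


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)} to TOML")


def dumps_toml(config: ModelConfig) -> str:
    """Serialize a configuration back to TOML (round-trips via load)."""
    out = []
    for block, values in config.model_dump().items():
        out.append(f"[{block}]")
        for key, val in values.items():
            if val is None:
                continue
            if isinstance(val, dict):
                for sub, sv in val.items():
                    out.append(f"{key}.{sub} = {_toml_value(sv)}")
            else:
                out.append(f"{key} = {_toml_value(val)}")
        out.append("")
    return "\n".join(out)


def config_hash(config: ModelConfig) -> str:
    """Deterministic sha256 digest of the full configuration."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
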