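"""Convenience layer: run the model directly from a :class:`ModelConfig`."""

from __future__ import annotations

from typing import Sequence

from .config import ModelConfig
from .steady_state import (SteadyStateSolution, SweepResult,
                           solve_operating_point, sweep)
from .stoichiometry import ProcessStoichiometry, process_reaction


def configured_stoichiometry(config: ModelConfig,
                             mu: float | None = None) -> ProcessStoichiometry:
    """Process-reaction stoichiometry at ``mu`` (default: the dilution rate)."""
    if mu is None:
        mu = config.operation.dilution_rate_per_h
    return process_reaction(mu, config.kinetic_parameters(),
                            biomass=config.biomass_formula(),
                            substrate=config.substrate_formula())


def solve_config(config: ModelConfig) -> SteadyStateSolution:
    """Converge the steady state defined by a configuration."""
    return solve_operating_point(
        config.operating_point(), configured_stoichiometry(config),
        geometry=config.reactor_geometry(),
        props=config.physical_properties(),
        corr=config.correlation_set())


def sweep_config(config: ModelConfig,
                 vsG_mean_grid: Sequence[float]) -> SweepResult:
    """Solve the configured operating point over a mean-velocity grid."""
    return sweep(config.operating_point(), vsG_mean_grid,
                 configured_stoichiometry(config),
                 geometry=config.reactor_geometry(),
                 props=config.physical_properties(),
                 corr=config.correlation_set())
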