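"""Exception hierarchy for the reactor model."""


class ScpReactorError(Exception):
    """Base class for all model errors."""


class DomainError(ScpReactorError, ValueError):
    """An input lies outside the physical or correlation-validity domain."""


class UnknownGasError(ScpReactorError, KeyError):
    """A gas species is not in the supported property set."""


class InvalidFormulaError(ScpReactorError, ValueError):
    """A molecular formula could not be parsed or is empty."""


class WashoutError(ScpReactorError):
    """No chemostat steady state: the requested growth rate cannot be sustained."""


class SaturationError(ScpReactorError):
    """Total pressure at or below the water vapor pressure: the gas phase
    cannot carry the required water."""


class InfeasibleCompositionError(ScpReactorError):
    """A gas-phase composition with a negative mole fraction was produced."""


class NoSteadyStateError(ScpReactorError):
    """The gas-phase balance has no root: transfer cannot meet the metabolic
    demand at any bottom superficial velocity."""


class DegenerateDesignError(ScpReactorError):
    """A cooling-loop or regime quantity is undefined (zero flow or zero rate)."""


class ConfigError(ScpReactorError, ValueError):
    """Configuration file is unparsable, has unknown keys, or out-of-range values."""
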