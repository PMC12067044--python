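"""Growth-rate-dependent process-reaction stoichiometry.

The chemostat couples the specific growth rate mu to the dilution rate D.
Substrate uptake follows the Herbert-Pirt partition into growth and
maintenance,

    -q_S = mu / Y_xs_max(molar) + m_S        [mol_S/(mol_x h)]

and the residual substrate concentration follows from inverting the Monod
(hyperbolic) uptake law  q_S = q_S_max C_S/(K_S + C_S).

Given -q_S per unit growth, the remaining coefficients of the process
reaction

    nu_S S + nu_O2 O2 + nu_NH3 NH3  ->  1 x + nu_CO2 CO2 + nu_H2O H2O

are fixed by the C, H, O, N element balances together with the
degree-of-reduction (electron) balance, gamma = 4C + H - 2O - 3N with NH3 as
the nitrogen reference.  Four of the five balances determine the four
unknown coefficients; the fifth is redundant and its residual is kept as a
closure check.  Consumption coefficients are stored negative.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import InvalidFormulaError, WashoutError

logger = logging.getLogger(__name__)

ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999, "N": 14.007}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


@dataclass(frozen=True)
class MolecularFormula:
    """Elemental composition C/H/O/N of one mole of a compound.

    Fractional atom counts are allowed (C-molar biomass formulas).
    ``molar_mass_override`` replaces the computed molar mass where a
    conventional rounded value is the field standard (e.g. 24.6 g/mol for
    CH1.8O0.5N0.2 biomass); it must stay consistent with the atom counts.
    """

    C: float = 0.0
    H: float = 0.0
    O: float = 0.0
    N: float = 0.0
    molar_mass_override: float | None = None

    def __post_init__(self) -> None:
        if self.molar_mass_override is not None:
            computed = (self.C * ATOMIC_MASS["C"] + self.H * ATOMIC_MASS["H"]
                        + self.O * ATOMIC_MASS["O"] + self.N * ATOMIC_MASS["N"])
            if abs(self.molar_mass_override - computed) > 0.01 * computed:
                raise InvalidFormulaError(
                    f"molar_mass_override {self.molar_mass_override} differs "
                    f"more than 1% from the computed {computed:.3f} g/mol")
        counts = (self.C, self.H, self.O, self.N)
        if any(c < 0 for c in counts):
            raise InvalidFormulaError(f"negative atom count in {self}")
        if all(c == 0 for c in counts):
            raise InvalidFormulaError("empty formula (all atom counts zero)")

    @classmethod
    def from_string(cls, formula: str) -> "MolecularFormula":
        """Parse e.g. ``"C2H6O"`` or ``"CH1.8O0.5N0.2"``."""
        if not formula or not formula.strip():
            raise InvalidFormulaError("empty formula string")
        counts = {"C": 0.0, "H": 0.0, "O": 0.0, "N": 0.0}
        pos = 0
        for m in _FORMULA_TOKEN.finditer(formula.strip()):
            if m.start() != pos:
                raise InvalidFormulaError(f"cannot parse formula {formula!r}")
            pos = m.end()
            elem, num = m.group(1), m.group(2)
            if elem not in counts:
                raise InvalidFormulaError(
                    f"unsupported element {elem!r} in {formula!r} "
                    f"(supported: C, H, O, N)")
            counts[elem] += float(num) if num else 1.0
        if pos != len(formula.strip()):
            raise InvalidFormulaError(f"cannot parse formula {formula!r}")
        return cls(**counts)

    @property
    def molar_mass(self) -> float:
        """g/mol, consistent with the atom counts."""
        if self.molar_mass_override is not None:
            return self.molar_mass_override
        return (self.C * ATOMIC_MASS["C"] + self.H * ATOMIC_MASS["H"]
                + self.O * ATOMIC_MASS["O"] + self.N * ATOMIC_MASS["N"])

    @property
    def gamma(self) -> float:
        """Degree of reduction, mol electrons per mol (NH3 as N reference)."""
        return 4.0 * self.C + self.H - 2.0 * self.O - 3.0 * self.N


#: Standard dry-cell composition, ash-free; the conventional rounded molar
#: mass 24.6 g/mol is used (exact atomic masses give 24.63).
BIOMASS = MolecularFormula(C=1.0, H=1.8, O=0.5, N=0.2,
                           molar_mass_override=24.6)
ETHANOL = MolecularFormula.from_string("C2H6O")
_O2 = MolecularFormula(O=2.0)
_CO2 = MolecularFormula(C=1.0, O=2.0)
_H2O = MolecularFormula(H=2.0, O=1.0)
_NH3 = MolecularFormula(H=3.0, N=1.0)

M_O2 = _O2.molar_mass
M_CO2 = _CO2.molar_mass
M_H2O = _H2O.molar_mass
M_NH3 = _NH3.molar_mass


def degree_of_reduction(formula: MolecularFormula) -> float:
    """gamma = 4C + H - 2O - 3N, mol electrons per mol of compound."""
    return formula.gamma


@dataclass(frozen=True)
class KineticParameters:
    """Monod/Herbert-Pirt parameters of the production organism.

    ``qS_max`` defaults to the Herbert-Pirt value at mu_max,
    mu_max/Y_xs_max(molar) + m_S, when left ``None``.
    """

    mu_max: float = 0.22          # 1/h
    K_S: float = 5.0e-4           # mol/kg_L
    Y_xs_max: float = 0.63        # g_x/g_S
    m_S: float = 0.005            # mol_S/(mol_x h)
    qS_max: float | None = None   # mol_S/(mol_x h)

    def __post_init__(self) -> None:
        for name in ("mu_max", "K_S", "Y_xs_max", "m_S"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.qS_max is not None and self.qS_max <= 0:
            raise ValueError("qS_max must be positive")

    def yield_molar(self, biomass: MolecularFormula = BIOMASS,
                    substrate: MolecularFormula = ETHANOL) -> float:
        """Y_xs_max converted to mol_x/mol_S."""
        return self.Y_xs_max * substrate.molar_mass / biomass.molar_mass

    def qS_max_effective(self, biomass: MolecularFormula = BIOMASS,
                         substrate: MolecularFormula = ETHANOL) -> float:
        if self.qS_max is not None:
            return self.qS_max
        return self.mu_max / self.yield_molar(biomass, substrate) + self.m_S


@dataclass(frozen=True)
class ProcessStoichiometry:
    """Converged process-reaction coefficients at one growth rate.

    ``nu`` holds mol_i per mol biomass with consumption negative; the biomass
    coefficient is +1 by construction.  ``closure_residual`` is the relative
    residual of the redundant (oxygen) element balance.
    """

    mu: float
    nu: Mapping[str, float]
    RQ: float
    Y_xs: float
    qS: float                       # signed, mol_S/(mol_x h), negative
    residual_CS: float              # mol/kg_L
    biomass: MolecularFormula = BIOMASS
    substrate: MolecularFormula = ETHANOL
    closure_residual: float = 0.0

    @property
    def nu_O2(self) -> float:
        return self.nu["O2"]

    @property
    def nu_CO2(self) -> float:
        return self.nu["CO2"]

    @property
    def nu_S(self) -> float:
        return self.nu["substrate"]

    @property
    def nu_NH3(self) -> float:
        return self.nu["NH3"]


def substrate_uptake(mu: float, params: KineticParameters,
                     biomass: MolecularFormula = BIOMASS,
                     substrate: MolecularFormula = ETHANOL,
                     ) -> tuple[float, float]:
    """Herbert-Pirt uptake and Monod-inverted residual concentration.

    Returns ``(qS, C_S)`` with ``qS`` signed (negative = consumption) in
    mol_S/(mol_x h) and ``C_S`` the chemostat residual substrate
    concentration in mol/kg_L.

    Raises
    ------
    WashoutError
        If ``mu >= mu_max`` or the required uptake reaches ``qS_max``: the
        chemostat has no steady state (washout).
    """
    if mu < 0:
        raise ValueError(f"growth rate must be non-negative, got {mu}")
    if mu >= params.mu_max:
        raise WashoutError(
            f"mu = {mu} 1/h >= mu_max = {params.mu_max} 1/h: washout")
    qS_abs = mu / params.yield_molar(biomass, substrate) + params.m_S
    qS_max = params.qS_max_effective(biomass, substrate)
    if qS_abs >= qS_max:
        raise WashoutError(
            f"required uptake {qS_abs:.4g} >= qS_max {qS_max:.4g} "
            "mol_S/(mol_x h): washout")
    C_S = params.K_S * qS_abs / (qS_max - qS_abs)
    return -qS_abs, C_S


def process_reaction(mu: float, params: KineticParameters,
                     biomass: MolecularFormula = BIOMASS,
                     substrate: MolecularFormula = ETHANOL,
                     ) -> ProcessStoichiometry:
    """Solve the growth-reaction coefficients at specific growth rate ``mu``.

    Per mole of biomass formed, the substrate coefficient is qS/mu and the
    O2, CO2, H2O and NH3 coefficients follow from the linear system of the
    C, N, electron and H balances; the O balance is the redundant closure
    check (relative residual logged and stored).
    """
    if mu <= 0:
        raise ValueError(f"process_reaction requires mu > 0, got {mu}")
    qS, C_S = substrate_uptake(mu, params, biomass, substrate)
    nu_S = qS / mu  # negative

    # unknowns: [nu_O2, nu_CO2, nu_H2O, nu_NH3]
    A = np.array([
        [0.0, 1.0, 0.0, 0.0],   # carbon
        [0.0, 0.0, 0.0, 1.0],   # nitrogen
        [-4.0, 0.0, 0.0, 0.0],  # electrons (gamma_O2 = -4)
        [0.0, 0.0, 2.0, 3.0],   # hydrogen
    ])
    b = -np.array([
        nu_S * substrate.C + biomass.C,
        nu_S * substrate.N + biomass.N,
        nu_S * substrate.gamma + biomass.gamma,
        nu_S * substrate.H + biomass.H,
    ])
    nu_O2, nu_CO2, nu_H2O, nu_NH3 = np.linalg.solve(A, b)

    # redundant oxygen balance
    o_terms = np.array([nu_S * substrate.O, biomass.O, 2.0 * nu_O2,
                        2.0 * nu_CO2, nu_H2O])
    closure = abs(o_terms.sum()) / np.abs(o_terms).max()
    logger.debug("redundant O-balance relative residual at mu=%g: %.3e",
                 mu, closure)

    nu = {"biomass": 1.0, "substrate": nu_S, "O2": nu_O2, "CO2": nu_CO2,
          "H2O": nu_H2O, "NH3": nu_NH3}
    return ProcessStoichiometry(
        mu=mu, nu=nu,
        RQ=nu_CO2 / (-nu_O2),
        Y_xs=(1.0 / -nu_S) * biomass.molar_mass / substrate.molar_mass,
        qS=qS, residual_CS=C_S,
        biomass=biomass, substrate=substrate,
        closure_residual=float(closure))
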