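import numpy as np
import pytest

import scpreactor as scp


@pytest.fixture(scope="session")
def config():
    return scp.load_config()


@pytest.fixture(scope="session")
def props():
    return scp.DEFAULT_PROPERTIES


@pytest.fixture(scope="session")
def geometry():
    return scp.ReactorGeometry()


@pytest.fixture(scope="session")
def kinetics():
    return scp.KineticParameters()


@pytest.fixture(scope="session")
def stoich(kinetics):
    """Process-reaction stoichiometry at the selected dilution rate 0.15 1/h."""
    return scp.process_reaction(0.15, kinetics)


@pytest.fixture(scope="session")
def base_case(stoich):
    """Pure O2, D = 0.15 1/h, vsG_mean = 0.30 m/s (maximum-transfer point)."""
    return scp.solve_operating_point(scp.OperatingPoint(vsG_mean=0.30), stoich)


@pytest.fixture(scope="session")
def low_velocity_case(stoich):
    """Pure O2, D = 0.15 1/h, vsG_mean = 0.04 m/s (regime lower bound)."""
    return scp.solve_operating_point(scp.OperatingPoint(vsG_mean=0.04), stoich)


@pytest.fixture(scope="session")
def base_sweep(stoich):
    grid = np.linspace(0.04, 0.30, 8)
    return scp.sweep(scp.OperatingPoint(), grid, stoich)


@pytest.fixture(scope="session")
def base_cooling(base_case):
    heat = scp.heat_balance(base_case)
    design = scp.size_cooling_system(heat, base_case.M_L)
    return heat, design
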