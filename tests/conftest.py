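import numpy as np
import pytest

import raftsim as rs

# printed source values, transcribed literally for fixture-fidelity checks
TABLE_MEMBRANE = {
    "Control": [27.06, 1.58, 13.73, 12.19, 15.71, 27.47, 2.26],
    "ADI/II": [25.24, 2.96, 10.66, 11.41, 17.72, 30.10, 1.92],
    "ADIII/IV": [24.05, 3.81, 11.16, 11.49, 16.53, 31.90, 1.06],
    "ADV/VI": [22.20, 4.51, 8.68, 10.69, 16.29, 35.67, 1.97],
}
TABLE_RAFTS = {
    "Control": [24.57, 1.20, 4.28, 3.95, 18.01, 33.54, 14.45],
    "ADI/II": [18.87, 5.57, 3.16, 4.95, 18.71, 38.26, 10.49],
    "ADIII/IV": [19.40, 5.33, 2.42, 4.90, 19.81, 38.03, 10.10],
    "ADV/VI": [23.78, 3.69, 3.66, 4.89, 11.31, 36.18, 16.49],
}
TABLE_CYLINDERS = {
    "cholesterol": (5.94, 19.99),
    "sterol_esters": (5.94, 19.99),
    "dha": (6.74, 19.01),
    "n6_lcpufa": (5.84, 19.70),
    "monoenes": (5.30, 22.59),
    "saturates": (6.14, 22.44),
    "sphingolipids": (6.18, 22.44),
}
INTERMOLECULAR_DISTANCE = 1.50


@pytest.fixture(scope="session")
def scenarios() -> rs.ScenarioSet:
    return rs.load_scenarios()


@pytest.fixture(scope="session")
def force_field(scenarios) -> rs.ForceField:
    return scenarios.force_field()


@pytest.fixture(scope="session")
def control_composition(scenarios) -> rs.MembraneComposition:
    return scenarios.membranes["Control"]


@pytest.fixture(scope="session")
def uniform_force_field() -> rs.ForceField:
    """Constant pair energies: no interaction contrast, free diffusion."""
    return rs.ForceField(
        energy=np.full((7, 7), 1e-19), settings=rs.InteractionSettings()
    )


def disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float):
    """Pixelated open disc; strict inequality keeps the pixel area and
    chords close to the continuous-geometry values used as oracle."""
    rr, cc = np.indices(shape)
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 < radius**2
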