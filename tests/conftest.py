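import numpy as np
import pytest

from glnfate.isotope_core import DEFAULT_ISOTOPES, ResolutionModel, parse_formula
from glnfate.synthetic_data import default_registry, scenario_presets
from glnfate.tracer_flux import load_default_atom_map

#: The metabolite panel of the tracing experiments.
PANEL_FORMULAS = {
    "glutamine": "C5H10N2O3",
    "glutamate": "C5H9NO4",
    "aspartate": "C4H7NO4",
    "alpha-ketoglutarate": "C5H6O5",
    "fumarate": "C4H4O4",
    "citrate": "C6H8O7",
    "IMP": "C10H13N4O8P",
    "AMP": "C10H14N5O7P",
    "GMP": "C10H14N5O8P",
    "UMP": "C9H13N2O9P",
}


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def atom_map():
    return load_default_atom_map()


@pytest.fixture(scope="session")
def presets():
    return scenario_presets()


@pytest.fixture(scope="session")
def orbitrap():
    """The instrument setting of the tracing measurements: 70,000 at m/z 200."""
    return ResolutionModel(r_ref=70000.0, mz_ref=200.0, exponent=0.5, separation_factor=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


def brute_force_isotopologue_mass(formula_text: str, n13c: int, n15n: int) -> float:
    """Independent oracle: per-atom sum over isotope masses, choosing n13c
    carbons as 13C, n15n nitrogens as 15N and the lightest isotope elsewhere."""
    formula = parse_formula(formula_text)
    total = 0.0
    for el, count in formula.counts.items():
        light = DEFAULT_ISOTOPES[el][0][0]
        if el == "C":
            heavy = DEFAULT_ISOTOPES["C"][1][0]
            total += n13c * heavy + (count - n13c) * light
        elif el == "N":
            heavy = DEFAULT_ISOTOPES["N"][1][0]
            total += n15n * heavy + (count - n15n) * light
        else:
            total += count * light
    return total
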