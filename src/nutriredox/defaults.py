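"""The package's reference ("glucose-addicted") configuration.

The default rate constants are *produced by the calibration module* from a
self-consistent steady-state constraint table shipped with the package
(``data/default_constraints.csv``): concentrations and fluxes of a high-GSH
reference steady state at abundant nutrients (10 mM glucose, 2 mM glutamine,
200 µM cystine), literature-style saturation constants and pool totals, and
fold activations for the signaling loops.  The configuration reflects a
glucose-addicted cell: high SLC7A11 expression, NADPH regeneration biased
strongly to the glucose/oxPPP route, and a substantial glutamate contribution
to ROS production.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

from .calibration import SteadyStateCalibration
from .io import read_constraints_csv
from .model import ModelParameters, NutrientEnvironment

__all__ = [
    "reference_environment",
    "default_constraints",
    "default_parameters",
    "default_calibration",
]

#: Reference nutrient-replete environment (µM).
REFERENCE_GLC = 10_000.0
REFERENCE_GLN = 2_000.0
REFERENCE_CYS2 = 200.0


def reference_environment() -> NutrientEnvironment:
    """Abundant-nutrient reference condition used for calibration."""
    return NutrientEnvironment(REFERENCE_GLC, REFERENCE_GLN, REFERENCE_CYS2)


@lru_cache(maxsize=1)
def default_constraints():
    """The shipped steady-state constraint table."""
    with resources.files("nutriredox").joinpath("data/default_constraints.csv").open() as f:
        return read_constraints_csv(f)


@lru_cache(maxsize=1)
def default_calibration():
    """Calibration result for the shipped constraint table."""
    return SteadyStateCalibration(default_constraints()).fit()


def default_parameters() -> ModelParameters:
    """Default glucose-addicted parameter set (calibrated at import time)."""
    return default_calibration().params
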