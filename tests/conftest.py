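import math

import numpy as np
import pytest

from qlmac.model import CellState, ParameterSet, basal_state
from qlmac.perturbations import PerturbationSpec, configure_params


@pytest.fixture(scope="session")
def params() -> ParameterSet:
    return ParameterSet()


@pytest.fixture(scope="session")
def zero_params() -> dict:
    """All rate constants zero (frozen system); fbd flag off."""
    d = {f: 0.0 for f in ParameterSet().to_dict()}
    d["fbd_on"] = False
    return d


@pytest.fixture(scope="session")
def basal(params) -> CellState:
    """Equilibrated resting state of the mean cell (no stimulus)."""
    return basal_state(configure_params(params, PerturbationSpec()))


@pytest.fixture(scope="session")
def basal_lps(params) -> CellState:
    """Resting state under the FBD-on parameterization used for LPS runs."""
    return basal_state(configure_params(params, PerturbationSpec(lps=100.0)))
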