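import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

import clamap


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_population(rng):
    """A complete 200-line RIL population on a 100 cM / 51-marker map."""
    design = clamap.SimulationDesign(
        marker_positions_cM=np.arange(0.0, 101.0, 2.0),
        qtls=(clamap.QTL(34.5, 1.0),),
        heritability=0.2,
        n_lines=200,
    )
    return clamap.simulate_population(design, rng)


# ---------------------------------------------------------------------------
# Shared heavy simulation cells (computed once per session)

_REPS = 500
_SEED = 20240901
_cells: dict = {}


def experiment_cell(model, h2, scenario):
    key = (model, h2, scenario)
    if key not in _cells:
        _cells[key] = clamap.run_experiment(
            model, h2, scenario, reps=_REPS, seed=_SEED
        )
    return _cells[key]


@pytest.fixture(scope="session")
def cell_reps():
    return _REPS
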