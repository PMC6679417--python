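import numpy as np
import pandas as pd
import pytest

from troutsperm import (EffectConfig, StudyDesign, ViscosityTable,
                        derive_cells, generate_dataset)


@pytest.fixture(scope="session")
def default_dataset():
    """One study-scale synthetic dataset (16 males, 640 cells), seed 1."""
    return generate_dataset(StudyDesign(), EffectConfig.null(), seed=1)


@pytest.fixture(scope="session")
def derived(default_dataset):
    return derive_cells(default_dataset.cells_frame())


@pytest.fixture(scope="session")
def males_frame(default_dataset):
    return default_dataset.males_frame()


@pytest.fixture
def toy_viscosity():
    """Two-entry toy table with convenient bracket/interp arithmetic."""
    return ViscosityTable(entries={5.0: 2.0, 10.0: 1.0})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
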