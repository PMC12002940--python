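import sys
from pathlib import Path
from types import SimpleNamespace

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from genestrat.dip import DipParams, flag_reactive
from genestrat.io import CountMatrix
from genestrat.normalize import getmm_log2cpm
from genestrat.simulate import SimulationDesign, simulate_counts
from genestrat.stratify import classify_all


@pytest.fixture
def toy_counts():
    return CountMatrix(
        ["g1", "g2", "g3"], ["s1", "s2"],
        np.array([[0, 5], [10, 0], [2, 2]]),
    )


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic design, simulated once per session."""
    design = SimulationDesign(seed=1)
    cm, meta, lengths, truth = simulate_counts(design)
    return SimpleNamespace(design=design, counts=cm, meta=meta,
                           lengths=lengths, truth=truth)


@pytest.fixture(scope="session")
def default_pipeline(default_sim):
    """Normalize + classify + dip on the default synthetic dataset."""
    norm = getmm_log2cpm(default_sim.counts, default_sim.lengths)
    table = classify_all(norm, default_sim.meta)
    flag_reactive(table, norm, default_sim.meta, DipParams(seed=5))
    return SimpleNamespace(norm=norm, table=table, **vars(default_sim))
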