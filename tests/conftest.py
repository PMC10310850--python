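import numpy as np
import pandas as pd
import pytest

from ffed import design as D
from ffed.simulate import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def l8():
    return D.build_l8()


@pytest.fixture(scope="session")
def assigned(l8):
    return D.assign_factors(l8, D.default_factors())


@pytest.fixture(scope="session")
def study_sheet():
    """The study layout: 4 lines x L8 + full extra replicate + 4-run partial."""
    return D.default_sample_sheet()


@pytest.fixture(scope="session")
def single_rep_sheet(assigned):
    return D.make_sample_sheet(assigned, D.default_cell_lines())


@pytest.fixture(scope="session")
def null_counts(study_sheet):
    """2,000-gene null simulation (no planted effects) on the study sheet."""
    cfg = SimulationConfig(n_genes=2000, seed=2)
    counts, truth = simulate_counts(cfg, study_sheet)
    return counts, truth


@pytest.fixture(scope="session")
def spiked_counts(study_sheet):
    """100 of 2,000 genes spiked at log2FC = 1 for Pb."""
    spiked = [f"g{i:04d}" for i in range(1, 101)]
    cfg = SimulationConfig(
        n_genes=2000, seed=1, causal_sets={"Pb": {g: 1.0 for g in spiked}}
    )
    counts, truth = simulate_counts(cfg, study_sheet)
    return counts, truth, spiked
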