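import numpy as np
import pandas as pd
import pytest

from mixqc.design import MixtureDesign, build_manifest, make_default_design
from mixqc.ingest import ExpressionTable
from mixqc.selectivity import PureProfile
from mixqc.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_design():
    return make_default_design()


@pytest.fixture(scope="session")
def noise_free_sim(default_design):
    """Noise-free dataset: expected signals pass straight through."""
    return simulate_dataset(SimulationConfig(seed=11, depth=None), default_design)


@pytest.fixture(scope="session")
def ngs_sim(default_design):
    """Moderate-depth sequencing dataset with multinomial counting noise."""
    return simulate_dataset(
        SimulationConfig(seed=7, n_mirna=600, depth=500_000), default_design
    )


@pytest.fixture()
def small_profile():
    """Hand-sized pure profile covering each selectivity archetype."""
    return PureProfile(
        pd.DataFrame(
            {
                "liver": [100.0, 1.0, 9.0, 50.0, 30.0],
                "brain": [5.0, 50.0, 9.0, 40.0, 300.0],
                "placenta": [5.0, 50.0, 100.0, 60.0, 20.0],
            },
            index=[f"m{i}" for i in range(5)],
        )
    )


def make_table(values: np.ndarray, design, n_replicates=1, kind="counts", mode="full"):
    """Wrap a raw matrix in an ExpressionTable with a generated manifest."""
    manifest = build_manifest(design, n_replicates, mode)
    frame = pd.DataFrame(
        values,
        index=[f"m{i}" for i in range(len(values))],
        columns=manifest.sample_ids,
    )
    return ExpressionTable(frame, kind, manifest)
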