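import warnings

import numpy as np
import pandas as pd
import pytest

from collateralis.phantom import PhantomSpec, easy_spec, generate_phantom
from collateralis.pipeline import RunConfig, run_pipeline


@pytest.fixture(autouse=True)
def _quiet_subvoxel_warning():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="sub-voxel vessel radius")
        warnings.filterwarnings("ignore", message="empty foreground")
        yield


@pytest.fixture(scope="session")
def phantom_pair():
    """One easy-condition phantom shared across tests (volume, truth, spec)."""
    spec = easy_spec(seed=11)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        volume, truth = generate_phantom(spec)
    return volume, truth, spec


@pytest.fixture(scope="session")
def noise_free_pair():
    spec = easy_spec(seed=5, noise_level=0.0, ring_amplitude=0.0)
    volume, truth = generate_phantom(spec)
    return volume, truth, spec


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """A full default pipeline run at seed 3: (config, manifest, out_dir)."""
    out_dir = tmp_path_factory.mktemp("pipeline_run")
    config = RunConfig(seed=3)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        manifest = run_pipeline(config, out_dir)
    return config, manifest, out_dir


@pytest.fixture(scope="session")
def train_table(pipeline_run) -> pd.DataFrame:
    _, _, out_dir = pipeline_run
    return pd.read_csv(out_dir / "stage6_features" / "train_features.csv")


@pytest.fixture
def rng():
    return np.random.default_rng(42)
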