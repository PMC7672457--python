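import numpy as np
import pytest

from crckit.core_io import PipelineConfig
from crckit.pipeline import run_full
from crckit.synthetic import SyntheticDatasetConfig, generate_dataset


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """One synthetic bundle with a planted circuit, shared across tests."""
    out = tmp_path_factory.mktemp("bundle")
    paths, truth = generate_dataset(SyntheticDatasetConfig(seed=11), out)
    return out, paths, truth


@pytest.fixture(scope="session")
def default_run(default_bundle, tmp_path_factory):
    """Full pipeline results on the default bundle."""
    bundle_dir, _, truth = default_bundle
    out = tmp_path_factory.mktemp("run")
    manifest = run_full(bundle_dir, out, PipelineConfig(seed=11, n_perm=10000))
    return out, manifest, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
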