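import numpy as np
import pytest

from mumo import SimConfig, write_cohort
from mumo.data_model import read_manifest


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """A small generated cohort on disk (manifest path, records)."""
    root = tmp_path_factory.mktemp("cohort_tiny")
    manifest = write_cohort(SimConfig(n_patients=40, seed=7), root)
    return manifest, read_manifest(manifest)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
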