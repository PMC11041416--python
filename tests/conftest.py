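import numpy as np
import pytest

from hragree import cohort as ch
from hragree import ingest


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Small on-disk synthetic cohort (2 participants x 3 sessions,
    identity-shaped distortion with realistic noise)."""
    root = tmp_path_factory.mktemp("tiny_cohort")
    cfg = ch.cohort_preset("tiny")
    participants, manifest = ch.generate_cohort(cfg, master_seed=7, out_dir=root)
    return root, participants, manifest


@pytest.fixture(scope="session")
def tiny_sessions(tiny_dataset):
    root, participants, manifest = tiny_dataset
    sessions, exclusions = ingest.align_sessions(manifest, participants, root)
    assert sessions, "tiny fixture produced no paired sessions"
    return sessions


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
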