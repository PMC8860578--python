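import numpy as np
import pytest
from hypothesis import settings

import phasetally as pt

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def tome_and_config():
    """Small six-gene transcriptome with two miRNA targets."""
    cfg = pt.SimConfig(seed=31)
    return pt.simulate_transcriptome(cfg), cfg


@pytest.fixture(scope="session")
def sam_pair(tome_and_config, tmp_path_factory):
    """Two replicate SAM libraries simulated from the shared transcriptome."""
    tome, cfg = tome_and_config
    d = tmp_path_factory.mktemp("sam")
    paths = {}
    for i, lib in enumerate(["wt_1", "wt_2"]):
        reads = pt.simulate_sirna_reads(cfg, tome, n_reads=3000, library=i)
        path = d / f"{lib}.sam"
        pt.write_sam(reads, tome, path)
        paths[lib] = path
    return paths


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
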