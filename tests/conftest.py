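import dataclasses

import numpy as np
import pytest

import nfasym as nf


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_ang_dataset():
    """1-subject / 1-block ANG-protocol dataset (fast, deterministic)."""
    proto = dataclasses.replace(nf.ANG, n_blocks=1, n_practice=0)
    cfg = nf.SynthConfig(protocol=proto, n_subjects=1, seed=42)
    ds, truth = nf.generate_dataset(cfg)
    return ds, truth


@pytest.fixture(scope="session")
def heu_dataset():
    """HEU-protocol dataset at the published scale: 11 subjects, 6 blocks."""
    cfg = nf.SynthConfig(protocol=nf.HEU, n_subjects=11, seed=7)
    ds, truth = nf.generate_dataset(cfg)
    return ds, truth
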