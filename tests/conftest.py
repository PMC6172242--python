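import numpy as np
import pytest

from accessprobe import readproc, simdata
from accessprobe.thermo import EnergyModel


@pytest.fixture(scope="session")
def model():
    return EnergyModel()


@pytest.fixture(scope="session")
def scaffold():
    return simdata.default_scaffold()


@pytest.fixture(scope="session")
def small_bundle(scaffold):
    """A small synthetic dataset shared across read-processing tests."""
    cfg = simdata.SimConfig(n_probes=8, reads_per_probe=500, replicates=2,
                            ta_length=120, seed=11)
    return simdata.simulate_bundle(cfg, scaffold)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture(scope="session")
def tiny_references(scaffold):
    """Two single-probe references with known probe spans (no leader)."""
    probes = [
        {"probe_id": "p1", "probe_seq": "AAGGCCTTAAGG", "ta_id": "ta", "start": 1, "end": 12},
        {"probe_id": "p2", "probe_seq": "AAGGCCTTCCGG", "ta_id": "ta", "start": 13, "end": 24},
    ]
    return readproc.build_reference_library(probes, scaffold)
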