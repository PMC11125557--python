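import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from sclineage.simulate import SimulationConfig, simulate_dataset
from sclineage.sites import SiteObservation, SiteRead


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


def make_observation(
    rng, n_cells, kind="singleton", max_reads=3, min_reads=1, q_range=(1e-3, 0.2)
) -> SiteObservation:
    """Random small observation fixture with valid bulk genotype and reads."""
    width = 1 if kind == "singleton" else 2
    nucs = list("ACGT")
    if kind == "singleton":
        ref = str(rng.choice(nucs))
        bulk = (ref, ref)
        gsnv = None
    else:
        ref = str(rng.choice(nucs))
        g1, g2 = rng.choice(nucs, size=2, replace=False)
        bulk = (str(g1) + ref, str(g2) + ref)
        gsnv = 10
    cells = []
    for _ in range(n_cells):
        L = int(rng.integers(min_reads, max_reads + 1))
        reads = [
            SiteRead(
                "".join(rng.choice(nucs, size=width)),
                tuple(rng.uniform(*q_range, size=width)),
            )
            for _ in range(L)
        ]
        cells.append(reads)
    return SiteObservation(kind, 11, gsnv, bulk, cells)


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Noiseless study conditions: no dropout, no amplification error, deep coverage."""
    config = SimulationConfig(
        n_cells=10,
        genome_length=10_000,
        mutations_per_edge=10,
        phasing_frequency=1.0,
        p_ado=0.0,
        p_ae=0.0,
        coverage_rate=20.0,
        seed=101,
    )
    return simulate_dataset(config)


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy dataset shared by I/O and pipeline tests."""
    config = SimulationConfig(
        n_cells=6,
        genome_length=2_000,
        mutations_per_edge=2,
        phasing_frequency=1.0,
        p_ado=0.1,
        p_ae=1e-3,
        coverage_rate=10.0,
        seed=7,
    )
    return simulate_dataset(config)
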