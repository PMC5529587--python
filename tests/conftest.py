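import numpy as np
import pandas as pd
import pytest

from sparrowmhc.genotyping.matrix import RunMatrix
from sparrowmhc.simulate import SimConfig, simulate_population


@pytest.fixture(scope="session")
def default_pop():
    """One study-sized population under default (study-condition) settings."""
    return simulate_population(SimConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_config():
    cfg = SimConfig(seed=7)
    cfg.read_sim.error_rate = 0.0
    cfg.read_sim.chimera_rate = 0.0
    cfg.read_sim.amplification_sigma = 0.0
    cfg.read_sim.replicate_fraction = 1.0
    return cfg


def make_matrix(counts: dict[str, dict[str, int]], sequences: dict[str, str],
                run_id: str = "R1", replicate_links=None) -> RunMatrix:
    """Small hand-written run matrix: counts[sample][variant_id] = reads."""
    samples = sorted(counts)
    variants = sorted(sequences)
    mat = pd.DataFrame(0, index=samples, columns=variants, dtype=int)
    for s, row in counts.items():
        for v, n in row.items():
            mat.loc[s, v] = n
    return RunMatrix(run_id=run_id, counts=mat, sequences=dict(sequences),
                     replicate_links=replicate_links or [])


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
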