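import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from satevol.simgen import SimConfig, assemble_genomes, evolve_monomers


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture
def small_sim():
    """A two-species simulated genome with truth, shared across tests."""
    cfg = SimConfig(
        seed=11,
        tree="(A:2,B:2);",
        mu=0.01,
        homog_rate=2.0,
        n_het_arrays=4,
        het_copies=(4, 6),
        n_eu_copies=4,
        burn_in_diversity=0.03,
        eu_offset=0.05,
        subfam_fraction=0.25,
        n_genes=3,
    )
    monomers, fragment = evolve_monomers(cfg)
    genomes, truth = assemble_genomes(monomers, cfg, fragment)
    return cfg, genomes, truth, fragment


def reciprocal_overlap(a: tuple[int, int], b: tuple[int, int], frac: float = 0.8) -> bool:
    ov = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    return ov >= frac * (a[1] - a[0]) and ov >= frac * (b[1] - b[0])
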