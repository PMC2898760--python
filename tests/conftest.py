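import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from tagdge.reference import Transcript, build_reference
from tagdge.simulate import SimulationConfig, simulate_experiment


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260925)


@pytest.fixture()
def toy_transcripts():
    """Three hand-built transcripts: one two-site, one single-site, one
    without any usable CATG site."""
    return [
        Transcript("gA", "CATGCATG" + "T" * 17),  # two overlapping sites
        Transcript("gB", "GGG" + "CATG" + "A" * 17 + "CCC"),  # one site
        Transcript("gC", "A" * 40),  # no site
    ]


@pytest.fixture()
def toy_reference(toy_transcripts):
    return build_reference(toy_transcripts)


@pytest.fixture(scope="session")
def small_experiment():
    """A compact but fully featured two-condition experiment used by the
    filtering/mapping/pipeline tests."""
    cfg = SimulationConfig(
        n_genes=300, library_size=60_000, seed=7, min_usable_sites=2
    )
    return simulate_experiment(cfg, ("cond1", "cond2"))
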