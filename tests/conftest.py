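import numpy as np
import pytest

from mtclock.alignment import Alignment
from mtclock.simulate import default_cheetah_scenario, simulate_alignment
from mtclock.substitution import TN93GParams


@pytest.fixture(scope="session")
def tn93_params():
    return TN93GParams(
        base_freqs=(0.1, 0.2, 0.3, 0.4), rate_AG=2.0, rate_CT=3.0,
        rate_transversion=1.0, gamma_shape=0.4, n_categories=3,
    )


@pytest.fixture(scope="session")
def jc_params():
    return TN93GParams(gamma_shape=1.0, n_categories=1)


@pytest.fixture(scope="session")
def random_alignment4():
    rng = np.random.default_rng(7)
    taxa = ("A", "B", "C", "D")
    seqs = tuple("".join(rng.choice(list("ACGT"), 30)) for _ in taxa)
    return Alignment(taxa, seqs)


@pytest.fixture(scope="session")
def cheetah_sim_small():
    """3 kb cheetah-like simulation with its generating scenario."""
    scenario = default_cheetah_scenario(seed=11, length=3000)
    alignment, true_clock = simulate_alignment(scenario)
    return scenario, alignment, true_clock
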