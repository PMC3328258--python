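import numpy as np
import pytest

from codonrates import alignment, simulate


@pytest.fixture(scope="session")
def sim_pair_500():
    """A mid-divergence simulated pair (500 codons, t=0.5, kappa=2,
    omega=0.3) reused by several estimator tests."""
    a, b, truth = simulate.simulate_codon_pair(
        simulate.SimRegime(500, 0.5, 2.0, 0.3, seed=42)
    )
    return a, b, truth


@pytest.fixture(scope="session")
def sim_alignment_500(sim_pair_500):
    a, b, _ = sim_pair_500
    return alignment.filter_columns(alignment.CodonAlignment("sim500", a, b))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
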