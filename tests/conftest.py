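import numpy as np
import pytest

from azsearch import (
    LocusAlleleProbabilities,
    SyntheticPanelConfig,
    generate_panel,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240112)


@pytest.fixture
def random_locus_probs(rng):
    """Factory for random normalized per-haplotype probability pairs."""

    def make(n_alleles=None, locus_id="L"):
        n = int(n_alleles if n_alleles is not None else rng.integers(2, 26))
        return LocusAlleleProbabilities(
            locus_id=locus_id,
            a1=rng.dirichlet(np.ones(n)),
            a2=rng.dirichlet(np.ones(n)),
        )

    return make


@pytest.fixture(scope="session")
def small_panel():
    """A small synthetic panel shared by pipeline-level tests."""
    cfg = SyntheticPanelConfig(n_individuals=40, n_loci=6, accuracy=0.8,
                               alleles_per_locus=(4, 8), seed=11)
    return generate_panel(cfg)


def point_mass(n, idx):
    v = np.zeros(n)
    v[idx] = 1.0
    return v
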