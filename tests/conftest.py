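import numpy as np
import pytest

from sagkit.community import (make_taxon_profile, simulate_community,
                              synthesize_genome)

# balanced composition so every phylum appears even in small test cohorts
TEST_COMPOSITION = {
    "Patescibacteria": 0.3,
    "DPANN": 0.15,
    "Other-Bacteria": 0.4,
    "Other-Archaea": 0.15,
}


@pytest.fixture(scope="session")
def genome_pool():
    """Six synthesized genomes spanning styles and genetic codes."""
    cases = [
        ("Patescibacteria", "patesci_like", 301),
        ("Patescibacteria", "patesci_like", 310),  # seed with code 25
        ("DPANN", "dpann_like", 302),
        ("Other-Bacteria", "standard", 303),
        ("Other-Bacteria", "standard", 304),
        ("Other-Bacteria", "symbiont_like", 305),
    ]
    pool = []
    for ph, st, seed in cases:
        prof = make_taxon_profile(ph, st, seed)
        pool.append(synthesize_genome(prof, seed + 5000))
    return pool


@pytest.fixture(scope="session")
def small_community():
    return simulate_community(
        n_taxa=6, n_sags=24, cosort_rate=0.05, seed=42,
        composition=TEST_COMPOSITION)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200817)
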