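import pytest

from cicerkit.synthetic_data import GenomeSimConfig, simulate_genome


@pytest.fixture(scope="session")
def multi_scaffold_sim():
    """Two linkage groups cut into scaffolds (some reverse-oriented) plus
    unanchored scaffolds; shared by anchoring/IO round-trip tests."""
    cfg = GenomeSimConfig(
        n_linkage_groups=2,
        arm_length_bp=1_500_000,
        core_length_bp=1_000_000,
        n_scaffolds_per_lg=4,
        flip_every=2,
        n_unanchored=2,
        seed=11,
    )
    records, genes, repeats, markers, truth = simulate_genome(cfg)
    return cfg, records, genes, repeats, markers, truth


@pytest.fixture(scope="session")
def single_chromosome_sim():
    """One linkage group as a single scaffold with a 3 Mb pericentromeric
    core; shared by topography tests."""
    cfg = GenomeSimConfig(n_linkage_groups=1, seed=3)
    records, genes, repeats, markers, truth = simulate_genome(cfg)
    return cfg, records, genes, repeats, markers, truth
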