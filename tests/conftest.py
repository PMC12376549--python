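import pytest

from soilvirome import SynthConfig, generate_community


@pytest.fixture(scope="session")
def default_community():
    """One default synthetic community shared by read-only tests."""
    return generate_community(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def small_community():
    """Small community (<100 kb of sequence) for exhaustive-window oracles."""
    return generate_community(
        SynthConfig(seed=23, n_viral_contigs=14, n_host_contigs=4,
                    length_range=(2200, 6500), frac_true_viral=0.5,
                    n_spacers=8, n_decoy_spacers=4, n_trna_links=4,
                    n_homology_links=3, homology_block_len=1800,
                    plant_boundary_features=False)
    )


@pytest.fixture(scope="session")
def equal_abundance_community():
    """Community with equal planted abundances and lysogenic fraction 0.21."""
    return generate_community(
        SynthConfig(seed=5, n_viral_contigs=100, frac_lysogenic=0.21,
                    abundance_mode="equal")
    )
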