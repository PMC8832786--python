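import pytest

from nlrkit.synthetic_data import (SyntheticConfig, generate_contig_set,
                                   generate_motif_library)


@pytest.fixture(scope="session")
def library():
    """Default motif library with integrated-domain motifs."""
    return generate_motif_library(42, 3, 8, 4, 4)


@pytest.fixture(scope="session")
def clean_data(library):
    """Small all-complete, all-CNL synthetic assembly."""
    cfg = SyntheticConfig(seed=42, n_loci=12, n_contigs=16, intron_rate=0.3)
    return generate_contig_set(cfg, library)


@pytest.fixture(scope="session")
def variant_data(library):
    """Assembly with pseudogenes, partials, fusions and tandem loci."""
    cfg = SyntheticConfig(seed=5, n_loci=40, n_contigs=50,
                          pseudogene_rate=0.25, partial_rate=0.2,
                          id_fusion_rate=0.2, tandem_rate=0.15,
                          intron_rate=0.3)
    return generate_contig_set(cfg, library)
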