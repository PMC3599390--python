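import pytest

from nbslrr.motifs import load_paper_motifs, synthetic_rpw8_profile
from nbslrr.synthetic import SyntheticConfig, generate_genome


@pytest.fixture(scope="session")
def motif_library():
    return load_paper_motifs()


@pytest.fixture(scope="session")
def rpw8_profile():
    return synthetic_rpw8_profile()


@pytest.fixture(scope="session")
def default_genome():
    """Default 57-NBS-gene synthetic genome (divergence 0, planted clusters
    and duplicate pairs), shared across structure/pipeline tests."""
    return generate_genome(SyntheticConfig(seed=11))
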