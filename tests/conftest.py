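import pytest

from sclrtools.simulate import (
    ChemistryConfig,
    ErrorModel,
    make_barcode_whitelist,
    make_transcripts,
    simulate_reads,
)


@pytest.fixture(scope="session")
def chem() -> ChemistryConfig:
    return ChemistryConfig()


@pytest.fixture(scope="session")
def small_sim(chem):
    """10 cells x 20 molecules, error-free, no duplication."""
    whitelist = make_barcode_whitelist(10, seed=1)
    transcripts = make_transcripts(8, 300, seed=2)
    reads, truth = simulate_reads(
        whitelist, transcripts, molecules_per_cell=20, errors=ErrorModel(seed=3)
    )
    return whitelist, transcripts, reads, truth


@pytest.fixture(scope="session")
def dup_sim(chem):
    """20 cells with both duplication layers on, error-free."""
    whitelist = make_barcode_whitelist(20, seed=4)
    transcripts = make_transcripts(10, 300, seed=5)
    reads, truth = simulate_reads(
        whitelist,
        transcripts,
        molecules_per_cell=50,
        splint_dup_rate=0.5,
        tenx_dup_rate=0.5,
        errors=ErrorModel(seed=6),
    )
    return whitelist, transcripts, reads, truth
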