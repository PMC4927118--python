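import pytest

from cafba import BUILTIN_SECTOR_CONFIGS, load_builtin, prepare_model


@pytest.fixture(scope="session")
def core_model():
    """E. coli core reconstruction, classified and patched for glucose."""
    return prepare_model(
        load_builtin("e_coli_core"), BUILTIN_SECTOR_CONFIGS["e_coli_core"]
    )


@pytest.fixture(scope="session")
def genome_model():
    """Genome-scale E. coli reconstruction (iJO1366), glucose condition."""
    return prepare_model(
        load_builtin("iJO1366"), BUILTIN_SECTOR_CONFIGS["iJO1366"]
    )
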