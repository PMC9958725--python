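import pytest

from lantipipe import CORE_PEPTIDES, PeptideRecord


@pytest.fixture(scope="session")
def cores() -> dict:
    """Mature core peptides of the four bundled nisin variants."""
    return dict(CORE_PEPTIDES)


@pytest.fixture(scope="session")
def peptide_records(cores) -> list:
    return [PeptideRecord(k, v, variant_name=f"nisin {k}")
            for k, v in cores.items()]
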