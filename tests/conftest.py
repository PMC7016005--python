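import pytest

from enuscan.datasets import (
    load_candidate_panel,
    load_backcross_variants,
    load_ta_domain_peptide,
)
from enuscan.helix import get_scale


@pytest.fixture(scope="session")
def panel():
    """The bundled 16-candidate x 12-mouse Sanger genotype panel."""
    return load_candidate_panel()


@pytest.fixture(scope="session")
def backcross_calls():
    """The four chromosome-12 variants checked in the G10 backcross animal."""
    return load_backcross_variants()


@pytest.fixture(scope="session")
def ta_peptide():
    """(record_id, sequence, protein offset) of the TA-domain 13-mer."""
    return load_ta_domain_peptide()


@pytest.fixture(scope="session")
def cf_scale():
    """The bundled Chou-Fasman alpha-helix propensity scale."""
    return get_scale("chou_fasman_alpha")
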