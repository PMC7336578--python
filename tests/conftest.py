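import pytest

from ssu1_checkup.panel import load_panel
from ssu1_checkup.popgen import load_loci


@pytest.fixture(scope="session")
def panel():
    return load_panel()


@pytest.fixture(scope="session")
def loci():
    return load_loci()


@pytest.fixture(scope="session")
def cen16_allele_ids(panel):
    """The seven chromosome XVI (CEN16-linked) allele ids, largest first."""
    ids = [a.allele_id for a in panel.alleles if a.cen16_linked]
    assert len(ids) == 7
    return sorted(ids, key=lambda i: -panel.by_id(i).expected_size_bp)
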