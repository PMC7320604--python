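import pytest

from zoomsid.markers import parchment_markers, peptide_from_sequence
from zoomsid.reference import build_chains


@pytest.fixture(scope="session")
def marker_table():
    return parchment_markers()


@pytest.fixture(scope="session")
def panel_digests():
    """Fully-cleaved digests (both chains combined) of the synthetic panel."""
    from zoomsid.proteome import digest

    out = {}
    for taxon in ("Ovis", "Capra", "Bos", "Cervus"):
        a, b = build_chains(taxon)
        out[taxon] = digest(a, 0) + digest(b, 0)
    return out


@pytest.fixture
def make_peptide():
    """Wrap a bare sequence as a self-parented Peptide."""
    return peptide_from_sequence
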