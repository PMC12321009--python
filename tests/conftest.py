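import pytest

from ciflint.dictionary import build_store


@pytest.fixture(scope="session")
def store():
    """Dictionary store with only the bundled fixture dictionaries."""
    store, diagnostics = build_store()
    assert not diagnostics, [d.message for d in diagnostics]
    return store


@pytest.fixture()
def fig_fragment():
    """A data block with a four-column atom-site loop, as shown in hover examples."""
    return (
        "data_96107abs\n"
        "loop_\n"
        "_atom_site_label\n"
        "_atom_site_fract_x\n"
        "_atom_site_fract_y\n"
        "_atom_site_fract_z\n"
        "S1 0.25861(5) 0.57975(5) 0.52011(3)\n"
    )
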