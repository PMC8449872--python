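import pytest

from motifdist import build_background


@pytest.fixture(scope="session")
def equi_model():
    """Equiprobable i.i.d. nucleotide background."""
    return build_background({s: 0.25 for s in "ACGT"})


@pytest.fixture(scope="session")
def at_rich_model():
    """AT-rich i.i.d. background {A:0.4, C:0.1, G:0.1, T:0.4}."""
    return build_background({"A": 0.4, "C": 0.1, "G": 0.1, "T": 0.4})


@pytest.fixture(scope="session")
def gc_rich_model():
    """GC-rich i.i.d. background {A:0.15, C:0.35, G:0.35, T:0.15}."""
    return build_background({"A": 0.15, "C": 0.35, "G": 0.35, "T": 0.15})
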