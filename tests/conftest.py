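import pytest

from codonharmony import builtin_table, load_usage_table
from codonharmony import genetic_code as gcode


@pytest.fixture(scope="session")
def ecoli():
    """Bundled host-like fixture table (synthetic values)."""
    return builtin_table("ecoli")


@pytest.fixture(scope="session")
def mouse():
    """Bundled eukaryotic-donor fixture table (synthetic values)."""
    return builtin_table("mouse")


@pytest.fixture(scope="session")
def burkholderia():
    """Bundled GC-rich prokaryotic-donor fixture table."""
    return builtin_table("burkholderia")


def make_table(overrides=None, base=10.0, label="toy"):
    """Complete table with uniform family frequencies except *overrides*.

    With no overrides every synonym has equal usage: all per_aa_freq are
    1/k and every RCU is 100 — a convenient neutral background for
    hand-computed examples.
    """
    freqs = {c: base for c in gcode.SENSE_CODONS}
    freqs.update({c: base for c in gcode.STOP_CODONS})
    if overrides:
        freqs.update(overrides)
    return load_usage_table(freqs, species_label=label)


@pytest.fixture
def uniform_table():
    return make_table()


@pytest.fixture
def leu_table():
    """Table with the spec'd Leu counts {CTG:50, TTA:13, TTG:13, CTT:10,
    CTC:10, CTA:4}; every other family uniform."""
    return make_table(
        {"CTG": 50, "TTA": 13, "TTG": 13, "CTT": 10, "CTC": 10, "CTA": 4}
    )
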