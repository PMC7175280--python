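"""Standard genetic code bookkeeping: synonymous families and degeneracy classes.

Everything downstream that groups "synonymous codons" — relative codon usage,
the harmonization engines, %MinMax, the effective-number-of-codons estimator —
goes through this module. The code table itself comes from Biopython
(NCBI translation table 1).
"""
from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

#: Sentinel amino-acid symbol for the three stop codons.
STOP = "*"

_TABLE = unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid for the 61 sense codons, plus stops -> '*'.
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
CODON_TO_AA.update({c: STOP for c in _TABLE.stop_codons})

SENSE_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.forward_table))
STOP_CODONS: tuple[str, ...] = tuple(sorted(_TABLE.stop_codons))

#: amino acid -> sorted tuple of synonymous codons (stops under '*').
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in sorted(CODON_TO_AA):
    AA_TO_CODONS.setdefault(CODON_TO_AA[_codon], tuple())
    AA_TO_CODONS[CODON_TO_AA[_codon]] += (_codon,)

#: amino acid -> family size (1, 2, 3, 4 or 6); stops excluded.
DEGENERACY: dict[str, int] = {
    aa: len(codons) for aa, codons in AA_TO_CODONS.items() if aa != STOP
}

#: degeneracy class -> amino acids in it (9 two-fold, 1 three-fold,
#: 5 four-fold, 3 six-fold, 2 singletons Met/Trp).
DEGENERACY_CLASSES: dict[int, tuple[str, ...]] = {}
for _aa, _k in sorted(DEGENERACY.items()):
    DEGENERACY_CLASSES.setdefault(_k, tuple())
    DEGENERACY_CLASSES[_k] += (_aa,)

_VALID = frozenset("ACGT")


class CodonError(ValueError):
    """Raised for strings that are not valid DNA codons."""


def normalize_codon(codon: str) -> str:
    """Uppercase, convert RNA U to DNA T, and validate a single codon."""
    c = codon.strip().upper().replace("U", "T")
    if len(c) != 3 or not _VALID.issuperset(c):
        raise CodonError(f"not a valid DNA codon: {codon!r}")
    return c


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a codon; ``'*'`` for a stop."""
    return CODON_TO_AA[normalize_codon(codon)]


def is_stop(codon: str) -> bool:
    return normalize_codon(codon) in STOP_CODONS


def synonyms(codon: str) -> tuple[str, ...]:
    """All codons coding the same amino acid (including the input)."""
    return AA_TO_CODONS[translate_codon(codon)]


def split_codons(seq: str) -> list[str]:
    """Split an in-frame DNA string into codons.

    Raises :class:`CodonError` if the length is not a multiple of 3 or the
    alphabet is not plain ACGT (U is accepted and converted).
    """
    s = seq.strip().upper().replace("U", "T")
    if len(s) % 3:
        raise CodonError(
            f"sequence length {len(s)} is not a multiple of 3 (not in frame)"
        )
    bad = set(s) - _VALID
    if bad:
        pos = next(i for i, b in enumerate(s, start=1) if b in bad)
        raise CodonError(f"non-ACGT character {s[pos - 1]!r} at position {pos}")
    return [s[i:i + 3] for i in range(0, len(s), 3)]
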