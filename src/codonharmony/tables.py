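"""Codon usage tables and relative codon usage (relative adaptiveness).

A :class:`CodonUsageTable` holds one organism's codon usage — counts or
frequencies, the scale is irrelevant — and derives two per-codon statistics:

* ``per_aa_freq``: a codon's share among its synonyms (sums to 1 per family);
* ``rcu``: relative codon usage in percent, 100 × freq / max synonymous freq.
  An RCU of 100% marks the family's most abundant codon; by convention this
  corresponds to the most abundant cognate tRNA in the organism.

Two text dialects are parsed: Kazusa-style ``CODON freq (count)`` blocks
(RNA or DNA alphabet) and a plain 2-column ``codon<TAB>number`` TSV. Three
synthetic fixture tables (E. coli-like, mouse-like, Burkholderia-like) are
bundled for tests and demos; they are labelled stand-ins, not authoritative
usage data.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

from . import genetic_code as gc

__all__ = [
    "CodonUsageTable",
    "UsageTableFormatError",
    "UsageTableValidationError",
    "load_usage_table",
    "relative_usage",
    "builtin_table",
    "BUILTIN_TABLES",
]


class UsageTableFormatError(ValueError):
    """Unparseable input or keys that are not codons."""


class UsageTableValidationError(ValueError):
    """Structurally valid input that violates table invariants."""


_KAZUSA_FIELD = re.compile(
    r"([ACGUTacgut]{3})\s+([0-9]+(?:\.[0-9]+)?)(?:\s*\(\s*([0-9]+)\s*\))?"
)


@dataclass
class CodonUsageTable:
    """Per-species codon usage with derived relative-usage statistics."""

    species_label: str
    freqs: dict[str, float]                     # raw numbers, DNA codons
    rcu: dict[str, float] = field(default_factory=dict)
    per_aa_freq: dict[str, float] = field(default_factory=dict)
    has_stops: bool = True
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.rcu:
            self._derive()

    def _derive(self) -> None:
        families: dict[str, list[str]] = {}
        for codon in self.freqs:
            families.setdefault(gc.CODON_TO_AA[codon], []).append(codon)
        for aa, codons in sorted(families.items()):
            vals = [self.freqs[c] for c in codons]
            total, vmax = sum(vals), max(vals)
            if vmax <= 0:
                name = "stop" if aa == gc.STOP else aa
                raise UsageTableValidationError(
                    f"all-zero codon family for amino acid {name!r}"
                )
            for c in codons:
                self.per_aa_freq[c] = self.freqs[c] / total
                self.rcu[c] = 100.0 * self.freqs[c] / vmax
        self.has_stops = any(c in self.freqs for c in gc.STOP_CODONS)
        if not self.has_stops:
            self.warnings.append("stop codons absent from table")

    # -- convenience accessors -------------------------------------------
    def freq(self, codon: str) -> float:
        return self.freqs[gc.normalize_codon(codon)]

    def family_rcus(self, codon: str) -> list[tuple[str, float]]:
        """(codon, rcu) for every synonym of *codon*, sorted by codon."""
        return [(c, self.rcu[c]) for c in gc.synonyms(codon)]

    def rare_codons(self, threshold: float = 40.0) -> list[str]:
        """Sense codons with RCU strictly below *threshold* percent."""
        return [
            c for c in gc.SENSE_CODONS
            if c in self.rcu and self.rcu[c] < threshold
        ]


def _parse_kazusa(text: str) -> dict[str, float]:
    freqs: dict[str, float] = {}
    for line in text.splitlines():
        if line.lstrip().startswith("#"):
            continue
        for codon, freq, _count in _KAZUSA_FIELD.findall(line):
            key = gc.normalize_codon(codon)
            if key in freqs:
                raise UsageTableFormatError(f"duplicate codon {codon!r}")
            freqs[key] = float(freq)
    if not freqs:
        raise UsageTableFormatError("no codon entries found (kazusa dialect)")
    return freqs


def _parse_tsv(text: str) -> dict[str, float]:
    freqs: dict[str, float] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise UsageTableFormatError(
                f"line {lineno}: expected 'codon<TAB>number', got {line!r}"
            )
        try:
            key = gc.normalize_codon(parts[0])
        except gc.CodonError as exc:
            raise UsageTableFormatError(f"line {lineno}: {exc}") from exc
        if key in freqs:
            raise UsageTableFormatError(f"line {lineno}: duplicate codon")
        freqs[key] = float(parts[1])
    if not freqs:
        raise UsageTableFormatError("no codon entries found (tsv dialect)")
    return freqs


def load_usage_table(
    source: str | Path | Mapping[str, float],
    dialect: str | None = None,
    species_label: str | None = None,
    require_complete: bool = True,
) -> CodonUsageTable:
    """Load and validate a codon usage table.

    *source* may be a mapping codon -> nonnegative number, a path to a table
    file, or raw table text. *dialect* is ``"kazusa"`` or ``"tsv"``; when
    omitted it is inferred (a path suffix of ``.tsv`` or 2-column lines mean
    TSV, anything else Kazusa). With ``require_complete=False`` partial
    tables (missing whole families) are allowed — useful for toy examples.
    """
    label = species_label or "unnamed"
    if isinstance(source, Mapping):
        raw = dict(source)
    else:
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and Path(source).exists()
        ):
            path = Path(source)
            text = path.read_text()
            label = species_label or path.stem
            if dialect is None and path.suffix.lower() == ".tsv":
                dialect = "tsv"
        else:
            text = str(source)
        if dialect is None:
            dialect = "kazusa" if _KAZUSA_FIELD.search(text) and "(" in text else "tsv"
        if dialect == "kazusa":
            raw = _parse_kazusa(text)
        elif dialect == "tsv":
            raw = _parse_tsv(text)
        else:
            raise UsageTableFormatError(f"unknown dialect {dialect!r}")

    freqs: dict[str, float] = {}
    for codon, value in raw.items():
        try:
            key = gc.normalize_codon(str(codon))
        except gc.CodonError as exc:
            raise UsageTableFormatError(str(exc)) from exc
        value = float(value)
        if value < 0:
            raise UsageTableValidationError(
                f"negative usage value for codon {key}: {value}"
            )
        freqs[key] = value

    if require_complete:
        missing = [c for c in gc.SENSE_CODONS if c not in freqs]
        if missing:
            raise UsageTableValidationError(
                f"{len(missing)} sense codons missing (e.g. {missing[:5]})"
            )
    else:
        # drop incomplete families only if every present member would still
        # normalise sensibly; partial families are normalised over what's there
        pass

    return CodonUsageTable(species_label=label, freqs=freqs)


def relative_usage(
    table: CodonUsageTable, codon: str, allow_stop: bool = False
) -> float:
    """RCU of *codon* in percent: 100 × freq / max synonymous freq."""
    key = gc.normalize_codon(codon)
    if gc.CODON_TO_AA[key] == gc.STOP and not allow_stop:
        raise UsageTableValidationError(
            f"{key} is a stop codon; pass allow_stop=True to score it"
        )
    if key not in table.rcu:
        raise UsageTableValidationError(
            f"codon {key} absent from table {table.species_label!r}"
        )
    return table.rcu[key]


BUILTIN_TABLES = {
    "ecoli": "ecoli_like.kazusa.txt",
    "mouse": "mouse_like.kazusa.txt",
    "burkholderia": "burkholderia_like.kazusa.txt",
}


def builtin_table(name: str) -> CodonUsageTable:
    """Load a bundled synthetic fixture table by short name.

    Names: ``ecoli``, ``mouse``, ``burkholderia``. These emulate a host,
    a eukaryotic donor and a GC-rich prokaryotic donor; their numbers are
    synthetic, not measured usage data.
    """
    try:
        fname = BUILTIN_TABLES[name]
    except KeyError:
        raise KeyError(
            f"unknown builtin table {name!r}; choices: {sorted(BUILTIN_TABLES)}"
        ) from None
    text = resources.files("codonharmony.data").joinpath(fname).read_text()
    return load_usage_table(text, dialect="kazusa", species_label=f"{name}-like")
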